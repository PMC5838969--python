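"""Call rates, denominators, heterozygosity, systematic failures, repeats."""

import numpy as np
import pandas as pd
import pytest

from arrayqc import sample_qc
from arrayqc.genotype_io import AA, AB, BB, NC
from conftest import make_calls, make_cohort


def test_denominators_without_failures_equal_probe_count():
    assert sample_qc.denominators_from_failure_counts(100, 0, 0) == {
        "gDNA": 100, "wgaDNA": 100}


def test_denominators_from_constructed_failure_patterns():
    # P0 ok everywhere, P1 fails everything, P2 fails wgaDNA only
    calls = make_calls({
        "g1": [AA, NC, AA], "g2": [AA, NC, AB],
        "w1": [BB, NC, NC], "w2": [AB, NC, NC]})
    cohort = make_cohort([("g1", "I1", "gDNA"), ("g2", "I2", "gDNA"),
                          ("w1", "I3", "wgaDNA"), ("w2", "I4", "wgaDNA")])
    denom = sample_qc.compute_denominators(calls, cohort)
    assert denom.n_failed_all == 1
    assert denom.n_failed_wga_only == 1
    assert denom.denominators == {"gDNA": 2, "wgaDNA": 1}


def test_empty_call_table_rejected():
    with pytest.raises(ValueError, match="empty"):
        sample_qc.compute_denominators(
            make_calls({}), make_cohort([("s", "i", "gDNA")]))


def test_call_rate_boundary_exactly_95_percent_passes():
    genos = {"s95": [AA] * 95 + [NC] * 5, "s94": [AA] * 94 + [NC] * 6,
             "s100": [AA] * 100}
    calls = make_calls(genos)
    cohort = make_cohort([(s, s, "gDNA") for s in genos])
    rates = sample_qc.compute_call_rates(calls, {"gDNA": 100, "wgaDNA": 100},
                                         cohort)
    by = rates.set_index("sample_id")
    assert by.loc["s95", "call_rate"] == 0.95 and by.loc["s95", "passes"]
    assert not by.loc["s94", "passes"]
    assert by.loc["s100", "call_rate"] == 1.0


def test_informative_counts_recover_truth_exactly(small_sim):
    calls, truth, cohort = (small_sim["calls"], small_sim["truth"],
                            small_sim["cohort"])
    denom = sample_qc.compute_denominators(calls, cohort)
    rates = sample_qc.compute_call_rates(calls, denom.denominators, cohort)
    n_probes = len(small_sim["manifest"])
    expect = n_probes - truth.nocall_mask.sum(axis=1)
    got = rates.set_index("sample_id")["n_informative"]
    assert (got.reindex(truth.sample_order).to_numpy() == expect).all()


def test_call_rates_invariant_under_row_order(small_sim):
    calls, cohort = small_sim["calls"], small_sim["cohort"]
    denom = sample_qc.compute_denominators(calls, cohort).denominators
    a = sample_qc.compute_call_rates(calls, denom, cohort)
    shuffled = calls.sample(frac=1.0, random_state=0)
    b = sample_qc.compute_call_rates(shuffled, denom, cohort)
    pd.testing.assert_frame_equal(a, b)


def test_chip_with_all_four_failing_excluded_three_flagged():
    samples = [(f"s{i}", f"i{i}", "gDNA") for i in range(12)]
    cohort = make_cohort(samples)  # chips of 4 in order
    rates = pd.DataFrame({
        "sample_id": [s[0] for s in samples],
        "passes": [False] * 4 + [False, False, False, True] + [True] * 4})
    chips, _ = sample_qc.detect_systematic_failures(rates, cohort)
    by = chips.set_index("chip_id")["action"]
    assert by["C0000"] == "exclude"
    assert by["C0001"] == "flag"
    assert "C0002" not in by.index


def test_all_passing_yields_no_chip_reports():
    samples = [(f"s{i}", f"i{i}", "gDNA") for i in range(8)]
    cohort = make_cohort(samples)
    rates = pd.DataFrame({"sample_id": [s[0] for s in samples],
                          "passes": [True] * 8})
    chips, plates = sample_qc.detect_systematic_failures(rates, cohort)
    assert len(chips) == 0 and len(plates) == 0


def test_plate_level_excess_failure_flagged():
    # 200 samples: plate PL000 (96) fails heavily, others barely
    samples = [(f"s{i}", f"i{i}", "gDNA") for i in range(200)]
    cohort = make_cohort(samples)
    fails = [(i < 60) for i in range(96)] + [False] * 104
    rates = pd.DataFrame({"sample_id": [s[0] for s in samples],
                          "passes": [not f for f in fails]})
    _, plates = sample_qc.detect_systematic_failures(rates, cohort)
    assert "PL000" in set(plates["plate_id"])
    assert "PL001" not in set(plates["plate_id"])


def test_heterozygosity_all_homozygous_is_zero_and_hwe_half():
    rng = np.random.default_rng(0)
    hwe = rng.binomial(2, 0.5, size=2000)
    calls = make_calls({"hom": [AA] * 100, "hwe": list(hwe)})
    manifest = pd.DataFrame({
        "probe_id": [f"P{i:06d}" for i in range(2000)],
        "chromosome": "chr1"})
    het = sample_qc.compute_heterozygosity(calls, manifest)
    by = het.set_index("sample_id")
    assert by.loc["hom", "het_rate"] == 0.0
    se = np.sqrt(0.25 / 2000)
    assert by.loc["hwe", "het_rate"] == pytest.approx(0.5, abs=4 * se)


def test_heterozygosity_excludes_sex_chromosomes():
    calls = make_calls({"s": [AB, AB, AA, AA]})
    manifest = pd.DataFrame({
        "probe_id": [f"P{i:06d}" for i in range(4)],
        "chromosome": ["chr1", "chrX", "chr1", "chrX"]})
    het = sample_qc.compute_heterozygosity(calls, manifest)
    assert het.loc[0, "n_called"] == 2
    assert het.loc[0, "het_rate"] == 0.5


def test_zero_called_genotypes_is_an_error():
    calls = make_calls({"s": [NC, NC]})
    manifest = pd.DataFrame({"probe_id": ["P000000", "P000001"],
                             "chromosome": "chr1"})
    with pytest.raises(ValueError, match="zero called"):
        sample_qc.compute_heterozygosity(calls, manifest)


def test_het_outlier_fences():
    base = pd.DataFrame({"sample_id": [f"s{i}" for i in range(50)],
                         "n_het": 0, "n_called": 1,
                         "het_rate": np.linspace(0.130, 0.144, 50),
                         "is_outlier": False})
    flagged = sample_qc.flag_het_outliers(base.copy())
    assert not flagged["is_outlier"].any()  # tight cluster, no outliers
    base.loc[0, "het_rate"] = 0.716
    flagged = sample_qc.flag_het_outliers(base.copy(), k=3)
    assert flagged.set_index("sample_id").loc["s0", "is_outlier"]
    flagged = sample_qc.flag_het_outliers(base.copy(), k=1e6)
    assert not flagged["is_outlier"].any()
    with pytest.raises(ValueError):
        sample_qc.flag_het_outliers(base.iloc[:3])


def test_failure_report_strata_sum_to_overall(small_sim):
    from arrayqc import sample_qc as sqc
    calls, cohort = small_sim["calls"], small_sim["cohort"]
    denom = sqc.compute_denominators(calls, cohort).denominators
    rates = sqc.compute_call_rates(calls, denom, cohort)
    report = sqc.failure_rate_report(rates, cohort)
    overall = report[(report["input_type"] == "all")].iloc[0]
    strata = report[(report["source_material"] != "all")]
    assert strata["n_failing"].sum() == overall["n_failing"]
    assert strata["n_samples"].sum() == overall["n_samples"]
    for itype in ("gDNA", "wgaDNA"):
        t_all = report[(report["input_type"] == itype)
                       & (report["source_material"] == "all")].iloc[0]
        t_str = strata[strata["input_type"] == itype]
        assert t_str["n_failing"].sum() == t_all["n_failing"]


def test_failure_report_single_clean_stratum_is_zero():
    rates = pd.DataFrame({"sample_id": ["a", "b"], "passes": [True, True],
                          "input_type": "gDNA", "source_material": "blood"})
    report = sample_qc.failure_rate_report(rates)
    assert (report["failure_pct"] == 0.0).all()


def test_select_repeats_union_and_reasons():
    rates = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                          "passes": [False, True, True, False]})
    het = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                        "het_rate": [0.2, 0.137, 0.7, 0.137],
                        "is_outlier": [True, False, True, False]})
    rep = sample_qc.select_repeats(rates, het).set_index("sample_id")
    assert set(rep.index) == {"a", "c", "d"}
    assert rep.loc["a", "reasons"] == "low_call_rate;het_outlier"
    assert rep.loc["c", "reasons"] == "het_outlier"
    assert rep.loc["d", "reasons"] == "low_call_rate"
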