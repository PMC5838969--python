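"""Replicate-pair and duplicate-locus concordance behaviour."""

import numpy as np
import pandas as pd
import pytest

from arrayqc import concordance
from arrayqc.genotype_io import AA, AB, BB, NC
from arrayqc.simulate import ReplicateDesign, SimulationConfig, simulate_all
from conftest import make_calls, make_cohort


def test_full_replicate_yields_six_typed_pairs():
    cohort = make_cohort([("g1", "I1", "gDNA"), ("g2", "I1", "gDNA"),
                          ("w1", "I1", "wgaDNA"), ("w2", "I1", "wgaDNA"),
                          ("x", "I2", "gDNA")])
    pairs = concordance.pair_replicates(cohort)
    assert len(pairs) == 6  # C(4,2); singleton I2 contributes none
    counts = pairs["pair_type"].value_counts()
    assert counts["gDNA-gDNA"] == 1
    assert counts["gDNA-wgaDNA"] == 4
    assert counts["wgaDNA-wgaDNA"] == 1


def test_pair_typing_is_order_symmetric():
    cohort = make_cohort([("w1", "I1", "wgaDNA"), ("g1", "I1", "gDNA")])
    pairs = concordance.pair_replicates(cohort)
    assert list(pairs["pair_type"]) == ["gDNA-wgaDNA"]


def test_failing_member_marks_pair_excluded():
    cohort = make_cohort([("g1", "I1", "gDNA"), ("w1", "I1", "wgaDNA")])
    rates = pd.DataFrame({"sample_id": ["g1", "w1"], "passes": [True, False]})
    pairs = concordance.pair_replicates(cohort, rates)
    assert not pairs["included"].iloc[0]


def test_identical_tables_give_unit_concordance_and_counts():
    genos = list(np.resize([AA, AB, BB], 1000))
    calls = make_calls({"a": genos, "b": genos})
    pairs = pd.DataFrame({"individual_id": ["I"], "sample_a": ["a"],
                          "sample_b": ["b"], "pair_type": ["gDNA-gDNA"],
                          "included": [True]})
    out = concordance.compute_pair_concordance(calls, pairs)
    assert out["concordance"].iloc[0] == 1.0
    assert out["n_both_called"].iloc[0] == 1000


def test_three_mismatches_in_thousand_give_0997():
    a = [AA] * 1000
    b = [AA] * 997 + [AB] * 3
    calls = make_calls({"a": a, "b": b})
    pairs = pd.DataFrame({"individual_id": ["I"], "sample_a": ["a"],
                          "sample_b": ["b"], "pair_type": ["gDNA-gDNA"],
                          "included": [True]})
    out = concordance.compute_pair_concordance(calls, pairs)
    assert out["concordance"].iloc[0] == pytest.approx(0.997)


def test_no_call_excluded_from_denominator():
    calls = make_calls({"a": [AA, NC, AB], "b": [AA, AB, NC]})
    pairs = pd.DataFrame({"individual_id": ["I"], "sample_a": ["a"],
                          "sample_b": ["b"], "pair_type": ["gDNA-gDNA"],
                          "included": [True]})
    out = concordance.compute_pair_concordance(calls, pairs)
    assert out["n_both_called"].iloc[0] == 1


def test_zero_cocalled_probes_is_an_error():
    calls = make_calls({"a": [AA, NC], "b": [NC, AA]})
    pairs = pd.DataFrame({"individual_id": ["I"], "sample_a": ["a"],
                          "sample_b": ["b"], "pair_type": ["gDNA-gDNA"],
                          "included": [True]})
    with pytest.raises(ValueError, match="no co-called"):
        concordance.compute_pair_concordance(calls, pairs)


def test_concordance_matches_symmetric_error_expectation():
    """Per-sample error rate e -> expected concordance (1-e)^2 + e^2/2."""
    e = 0.02
    cfg = SimulationConfig(
        seed=13, n_loci=5000, n_individuals=25,
        replicate_design=ReplicateDesign(0, 0, 25, 0),
        genotype_error_rate=e, dropout_vulnerability_coef=0.0,
        chip_fail_rate=0.0, plate_fail_rate=0.0, cnv_spec=[])
    _, cohort, calls, _, _ = simulate_all(cfg)
    pairs = concordance.pair_replicates(cohort)
    out = concordance.compute_pair_concordance(calls, pairs)
    expect = (1 - e) ** 2 + e ** 2 / 2
    n = out["n_both_called"].sum()
    se = np.sqrt(expect * (1 - expect) / n)
    observed = out["n_concordant"].sum() / n
    assert observed == pytest.approx(expect, abs=4 * se)


def test_summary_means_and_outlier_floor():
    pairs = pd.DataFrame({
        "individual_id": ["I1", "I2"], "sample_a": ["a", "c"],
        "sample_b": ["b", "d"], "pair_type": ["gDNA-gDNA"] * 2,
        "included": [True, True], "n_both_called": [1000, 1000],
        "n_concordant": [1000, 990], "concordance": [1.0, 0.99]})
    summary, outliers = concordance.summarize_concordance(pairs)
    assert summary["mean"].iloc[0] == pytest.approx(0.995)
    assert list(outliers["individual_id"]) == ["I2"]


def test_maf_from_genotype_counts():
    # 70 AA, 20 AB, 10 BB -> f_B = (20 + 20)/200 = 0.2
    genos = [AA] * 70 + [AB] * 20 + [BB] * 10
    calls = make_calls({f"s{i}": [g] for i, g in enumerate(genos)})
    cohort = make_cohort([(f"s{i}", f"i{i}", "gDNA") for i in range(100)])
    manifest = pd.DataFrame({"probe_id": ["P000000"], "locus_id": ["L0"],
                             "chromosome": ["chr1"], "position": [1]})
    maf = concordance.compute_maf(calls, cohort, manifest)
    assert maf["maf"].iloc[0] == pytest.approx(0.2)
    assert maf["n_individuals"].iloc[0] == 100


@pytest.mark.parametrize("geno,expect", [(AA, 0.0), (AB, 0.5)])
def test_maf_degenerate_inputs(geno, expect):
    calls = make_calls({"s1": [geno], "s2": [geno]})
    cohort = make_cohort([("s1", "i1", "gDNA"), ("s2", "i2", "gDNA")])
    manifest = pd.DataFrame({"probe_id": ["P000000"], "locus_id": ["L0"],
                             "chromosome": ["chr1"], "position": [1]})
    maf = concordance.compute_maf(calls, cohort, manifest)
    assert maf["maf"].iloc[0] == pytest.approx(expect)


def test_maf_uses_one_sample_per_individual_gdna_preferred():
    # individual i1 has a wgaDNA AA and a gDNA BB sample; gDNA must win
    calls = make_calls({"w": [AA], "g": [BB]})
    cohort = make_cohort([("w", "i1", "wgaDNA"), ("g", "i1", "gDNA")])
    manifest = pd.DataFrame({"probe_id": ["P000000"], "locus_id": ["L0"],
                             "chromosome": ["chr1"], "position": [1]})
    maf = concordance.compute_maf(calls, cohort, manifest)
    assert maf["f_b"].iloc[0] == pytest.approx(1.0)
    assert maf["n_individuals"].iloc[0] == 1


def _dup_manifest():
    return pd.DataFrame({
        "probe_id": ["P000000", "P000001"], "locus_id": ["L0", "L0"],
        "chromosome": ["chr1"] * 2, "position": [100, 100]})


def _dup_inputs(gdna_agree: int, gdna_total: int, wga_agree: int,
                wga_total: int):
    """Call table where duplicate-probe agreement rates are exact."""
    genos = {}
    cohort_rows = []
    for i in range(gdna_total):
        agree = i < gdna_agree
        genos[f"g{i}"] = [AA, AA if agree else AB]
        cohort_rows.append((f"g{i}", f"gi{i}", "gDNA"))
    for i in range(wga_total):
        agree = i < wga_agree
        genos[f"w{i}"] = [AA, AA if agree else AB]
        cohort_rows.append((f"w{i}", f"wi{i}", "wgaDNA"))
    return make_calls(genos), make_cohort(cohort_rows)


def test_duplicate_locus_classes_at_99_percent():
    maf = pd.DataFrame({"locus_id": ["L0"], "maf": [0.3], "f_b": [0.3],
                        "n_individuals": [1]})
    calls, cohort = _dup_inputs(200, 200, 196, 200)  # wga concordance 0.98
    per_locus, _ = concordance.duplicate_locus_concordance(
        calls, _dup_manifest(), maf, cohort)
    assert per_locus["class"].iloc[0] == "low_wga_only"
    calls, cohort = _dup_inputs(200, 200, 200, 200)
    per_locus, summary = concordance.duplicate_locus_concordance(
        calls, _dup_manifest(), maf, cohort)
    assert per_locus["class"].iloc[0] == "both_high"
    assert summary["class_pct"]["both_high"] == 100.0


def test_duplicate_aggregation_is_within_sample_all_probes_agree():
    """3 probes: a 2-1 split within a sample counts that sample discordant."""
    manifest = pd.DataFrame({
        "probe_id": ["P000000", "P000001", "P000002"],
        "locus_id": ["L0"] * 3, "chromosome": ["chr1"] * 3,
        "position": [100] * 3})
    calls = make_calls({"g0": [AA, AA, AB], "g1": [AA, AA, AA]})
    cohort = make_cohort([("g0", "i0", "gDNA"), ("g1", "i1", "gDNA"),
                          ("w0", "i2", "wgaDNA")])
    calls = pd.concat([calls, make_calls({"w0": [AA, AA, AA]})],
                      ignore_index=True)
    maf = pd.DataFrame({"locus_id": ["L0"], "maf": [0.3], "f_b": [0.3],
                        "n_individuals": [1]})
    per_locus, _ = concordance.duplicate_locus_concordance(
        calls, manifest, maf, cohort)
    assert per_locus["concordance_gdna"].iloc[0] == pytest.approx(0.5)


def test_concordance_invariant_to_probe_row_order(small_sim):
    calls, cohort = small_sim["calls"], small_sim["cohort"]
    pairs = concordance.pair_replicates(cohort)
    a = concordance.compute_pair_concordance(calls, pairs)
    shuffled = calls.sample(frac=1.0, random_state=1)
    b = concordance.compute_pair_concordance(shuffled, pairs)
    assert np.allclose(a["concordance"], b["concordance"])
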