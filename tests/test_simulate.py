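"""Generator behaviour: determinism, design structure, artifact truth."""

import numpy as np
import pandas as pd
import pytest

from arrayqc.genotype_io import AB, NC
from arrayqc.simulate import (AMEL, STR_MARKERS, ReplicateDesign,
                              SimulationConfig, generate_cohort,
                              generate_manifest, generate_str_profiles,
                              simulate_all)


def test_identical_seed_and_config_reproduce_everything(small_sim):
    cfg = small_sim["config"]
    man2, coh2, calls2, truth2, prof2 = simulate_all(cfg)
    pd.testing.assert_frame_equal(small_sim["manifest"], man2)
    pd.testing.assert_frame_equal(small_sim["cohort"], coh2)
    pd.testing.assert_frame_equal(small_sim["calls"], calls2)
    pd.testing.assert_frame_equal(small_sim["profiles"], prof2)
    assert np.array_equal(small_sim["truth"].nocall_mask, truth2.nocall_mask)


def test_manifest_probe_and_duplicate_counts():
    cfg = SimulationConfig(seed=3, n_loci=1000, duplicate_locus_fraction=0.015)
    manifest = generate_manifest(cfg)
    assert len(manifest) == 1000
    dup = manifest[manifest["locus_id"].duplicated(keep=False)]
    # 15 duplicated probes -> 15 second copies of 15 loci
    assert manifest["locus_id"].duplicated().sum() == 15
    for _, grp in dup.groupby("locus_id"):
        assert grp["position"].nunique() == 1
        assert grp["allele_a"].nunique() == 1


def test_manifest_sorted_by_chromosome_and_position():
    manifest = generate_manifest(SimulationConfig(seed=1, n_loci=500))
    for _, grp in manifest.groupby("chromosome"):
        assert grp["position"].is_monotonic_increasing


@pytest.mark.parametrize("kwargs", [
    {"chromosome_length_bp": 0},
    {"duplicate_locus_fraction": 0.6},
    {"n_loci": 50},
    {"n_individuals": 10},  # smaller than the default replicate design
])
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs).validate()


def test_cohort_replicate_structure_and_chips():
    cfg = SimulationConfig(seed=5, n_individuals=20,
                           replicate_design=ReplicateDesign(2, 1, 1, 1))
    cohort = generate_cohort(cfg)
    by_ind = cohort.groupby("individual_id")["input_type"].agg(list)
    full = by_ind["I0000"]
    assert len(full) == 4 and full.count("gDNA") == 2
    gw = by_ind["I0002"]
    assert sorted(gw) == ["gDNA", "wgaDNA"]
    assert (cohort.groupby("chip_id").size() <= 4).all()


def test_eight_singleton_samples_fill_two_chips():
    cfg = SimulationConfig(seed=5, n_individuals=8,
                           replicate_design=ReplicateDesign(0, 0, 0, 0))
    cohort = generate_cohort(cfg)
    assert len(cohort) == 8
    assert cohort["chip_id"].nunique() == 2


def test_no_call_conservation_against_truth(small_sim):
    """Every NC in the table comes from the injected mask, exactly."""
    calls, truth = small_sim["calls"], small_sim["truth"]
    assert (calls["genotype"] == NC).sum() == truth.nocall_mask.sum()
    per_sample = (calls[calls["genotype"] == NC]
                  .groupby("sample_id", observed=True).size())
    expect = pd.Series(truth.nocall_mask.sum(axis=1),
                       index=truth.sample_order)
    assert (per_sample.reindex(expect.index).fillna(0) == expect).all()


def test_zero_artifact_simulation_has_flat_lrr():
    cfg = SimulationConfig(
        seed=2, n_loci=300, n_individuals=12,
        replicate_design=ReplicateDesign(1, 1, 1, 1),
        gc_wave_amplitude=0.0, cpg_wave_amplitude=0.0, wave_sample_sd=0.0,
        chip_lrr_offset_sd=0.0, lrr_noise_sd=0.0, wga_noise_coef=0.0,
        noise_jitter_sd=0.0, cnv_spec=[])
    _, _, calls, _, _ = simulate_all(cfg)
    assert np.allclose(calls["lrr"], 0.0)


def test_dropout_reduces_observed_wga_heterozygosity_by_closed_form():
    """With marginal drop-out D on wgaDNA hets, observed het = h(1 - D)."""
    qm = {k: (0.5, 0.0) for k in SimulationConfig().quality_model}
    cfg = SimulationConfig(
        seed=11, n_loci=3000, n_individuals=60,
        replicate_design=ReplicateDesign(20, 0, 0, 0),
        quality_model=qm, genotype_error_rate=0.0,
        dropout_vulnerability_coef=0.4, dropout_given_vulnerable=0.5,
        chip_fail_rate=0.0, plate_fail_rate=0.0, cnv_spec=[])
    _, cohort, calls, _, _ = simulate_all(cfg)
    d_marginal = 0.4 * (1 - 0.5) * 0.5  # v(q) * P(drop | vulnerable)
    called = calls[calls["genotype"] != NC].merge(
        cohort[["sample_id", "input_type"]], on="sample_id")
    het = (called.groupby(["input_type", "sample_id"], observed=True)
           ["genotype"].apply(lambda g: (g == AB).mean()))
    ratio = het["wgaDNA"].mean() / het["gDNA"].mean()
    assert ratio == pytest.approx(1 - d_marginal, abs=0.012)


def test_str_profiles_clean_at_full_quality():
    cfg = SimulationConfig(seed=4, n_individuals=20,
                           replicate_design=ReplicateDesign(5, 0, 0, 0),
                           str_contamination_rate=0.0)
    cohort = generate_cohort(cfg)
    quality = pd.DataFrame({"sample_id": cohort["sample_id"], "q": 1.0})
    profiles, truth = generate_str_profiles(cohort, cfg, quality)
    by_sample = {s: dict(zip(g["marker"], g["alleles"]))
                 for s, g in profiles.groupby("sample_id")}
    truth_by_ind = {i: dict(zip(g["marker"], g["alleles"]))
                    for i, g in truth.groupby("individual_id")}
    for row in cohort.itertuples(index=False):
        assert by_sample[row.sample_id] == truth_by_ind[row.individual_id]


def test_amelogenin_follows_reported_sex(small_sim):
    cohort, profiles = small_sim["cohort"], small_sim["profiles"]
    amel = profiles[profiles["marker"] == AMEL].set_index("sample_id")["alleles"]
    for row in cohort.itertuples(index=False):
        expect = {"X", "Y"} if row.reported_sex == "M" else {"X"}
        assert set(amel[row.sample_id]) == expect


def test_str_dropout_matches_binomial_expectation():
    """Expected dropped markers ~= d x (het marker count) across samples."""
    cfg = SimulationConfig(seed=9, n_individuals=150,
                           replicate_design=ReplicateDesign(0, 150, 0, 0),
                           str_contamination_rate=0.0, str_failure_coef=0.0,
                           str_dropout_coef=0.4)
    cohort = generate_cohort(cfg)
    quality = pd.DataFrame({"sample_id": cohort["sample_id"], "q": 0.5})
    profiles, truth = generate_str_profiles(cohort, cfg, quality)
    d = 0.4 * (1 - 0.5)
    by_sample = {s: dict(zip(g["marker"], g["alleles"]))
                 for s, g in profiles.groupby("sample_id")}
    truth_by_ind = {i: dict(zip(g["marker"], g["alleles"]))
                    for i, g in truth.groupby("individual_id")}
    n_drop = n_het = 0
    for row in cohort[cohort["input_type"] == "wgaDNA"].itertuples(index=False):
        t = truth_by_ind[row.individual_id]
        w = by_sample[row.sample_id]
        for m in STR_MARKERS:
            if m == AMEL or len(t[m]) != 2:
                continue
            n_het += 1
            if w[m] < t[m] and len(w[m]) == 1:
                n_drop += 1
    se = np.sqrt(d * (1 - d) / n_het)
    assert n_drop / n_het == pytest.approx(d, abs=4 * se)
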