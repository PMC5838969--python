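"""STR-profile quality screen for whole-genome-amplified samples.

A 16-marker Identifiler-style profile (15 autosomal STRs plus
amelogenin) of each wgaDNA sample is compared against its source gDNA
profile: per marker the wgaDNA call is *fully concordant* (equal allele
sets), shows *allele drop-out* (a strict non-empty subset of the gDNA
alleles), is a *marker failure* (empty), or is otherwise discordant.
More than two alleles at two or more autosomal markers flags
contamination; amelogenin is checked against reported sex.  The marker
accounting always sums to the panel size.

Comparisons roll up into a quality category (high / intermediate /
poor; cutpoints configurable) used as a pre-genotyping screen: the
report cross-tabulates array failure rates by category and source
material and computes the counterfactual failure rate had poor-quality
samples been excluded before chip processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import STR_MARKERS, AMEL

PANEL_SIZE = len(STR_MARKERS)


@dataclass
class STRThresholds:
    high_min_concordant: int = 15
    high_max_failures: int = 0
    poor_min_dropout: int = 3
    poor_min_failures: int = 2


@dataclass
class STRComparison:
    individual_id: str
    sample_id: str
    n_markers_compared: int
    n_fully_concordant: int
    n_dropout: int
    n_marker_failures: int
    n_discordant_other: int
    contamination_flag: bool
    sex_concordant: bool | None
    quality_category: str = ""


def _profile_dict(profile: pd.DataFrame) -> dict:
    return dict(zip(profile["marker"], profile["alleles"]))


def compare_profiles(gdna: pd.DataFrame | dict, wga: pd.DataFrame | dict,
                     individual_id: str = "", sample_id: str = "",
                     reported_sex: str | None = None) -> STRComparison:
    """Marker-by-marker comparison of a gDNA/wgaDNA profile pair."""
    g = gdna if isinstance(gdna, dict) else _profile_dict(gdna)
    w = wga if isinstance(wga, dict) else _profile_dict(wga)
    if set(g) != set(STR_MARKERS) or set(w) != set(STR_MARKERS):
        raise ValueError("profiles must cover the full 16-marker panel")

    n_conc = n_drop = n_fail = n_other = 0
    n_multi = 0
    for m in STR_MARKERS:
        gs, ws = frozenset(g[m]), frozenset(w[m])
        if m != AMEL and len(ws) > 2:
            n_multi += 1
        if ws == gs:
            n_conc += 1
        elif not ws:
            n_fail += 1
        elif ws < gs:
            n_drop += 1
        else:
            n_other += 1

    sex_conc: bool | None = None
    if reported_sex in ("M", "F"):
        amel = frozenset(w[AMEL])
        observed = "M" if amel == frozenset({"X", "Y"}) else (
            "F" if amel == frozenset({"X"}) else None)
        sex_conc = observed == reported_sex if observed else False

    return STRComparison(
        individual_id=individual_id,
        sample_id=sample_id,
        n_markers_compared=PANEL_SIZE,
        n_fully_concordant=n_conc,
        n_dropout=n_drop,
        n_marker_failures=n_fail,
        n_discordant_other=n_other,
        contamination_flag=n_multi >= 2,
        sex_concordant=sex_conc,
    )


def quality_category(comparison: STRComparison,
                     thresholds: STRThresholds | None = None) -> str:
    """high / intermediate / poor from the marker accounting.

    Poor takes precedence: heavy drop-out, multiple marker failures or
    contamination marks a sample poor regardless of how many markers
    happened to agree.
    """
    th = thresholds or STRThresholds()
    if (comparison.n_dropout >= th.poor_min_dropout
            or comparison.n_marker_failures >= th.poor_min_failures
            or comparison.contamination_flag):
        return "poor"
    if (comparison.n_fully_concordant >= th.high_min_concordant
            and comparison.n_marker_failures <= th.high_max_failures):
        return "high"
    return "intermediate"


def compare_cohort(profiles: pd.DataFrame, cohort: pd.DataFrame,
                   thresholds: STRThresholds | None = None) -> pd.DataFrame:
    """Compare every wgaDNA sample against its source-gDNA profile.

    The gDNA side is the individual's first gDNA sample profile when one
    exists, else the ``SRC_<individual>`` source reference emitted by
    the simulator.
    """
    by_sample: dict[str, dict] = {
        s: _profile_dict(grp) for s, grp in profiles.groupby("sample_id")}
    rows = []
    for ind, grp in cohort.groupby("individual_id"):
        gdna_samples = grp.loc[grp["input_type"] == "gDNA", "sample_id"]
        ref_key = None
        for s in gdna_samples:
            if s in by_sample:
                ref_key = s
                break
        if ref_key is None and f"SRC_{ind}" in by_sample:
            ref_key = f"SRC_{ind}"
        if ref_key is None:
            continue
        sex = grp["reported_sex"].iloc[0]
        for s in grp.loc[grp["input_type"] == "wgaDNA", "sample_id"]:
            if s not in by_sample:
                continue
            cmp = compare_profiles(by_sample[ref_key], by_sample[s],
                                   individual_id=ind, sample_id=s,
                                   reported_sex=sex)
            cmp.quality_category = quality_category(cmp, thresholds)
            rows.append(cmp.__dict__)
    return pd.DataFrame(rows)


def screen_report(comparisons: pd.DataFrame, call_rates: pd.DataFrame,
                  cohort: pd.DataFrame):
    """Array failure rates by STR quality category + counterfactual rate.

    Returns ``(by_category, counterfactual)``: failure rates of wgaDNA
    samples cross-tabulated by quality category and source material,
    and the overall / per-source wgaDNA failure rates recomputed after
    excluding poor-category samples — what the study would have seen
    had the screen been applied before genotyping.
    """
    cr = call_rates
    if "source_material" not in cr.columns:
        cr = cr.merge(cohort[["sample_id", "source_material"]], on="sample_id")
    merged = comparisons[["sample_id", "quality_category"]].merge(
        cr[["sample_id", "source_material", "passes"]], on="sample_id")

    by_cat = (merged.groupby(["quality_category", "source_material"])
              .agg(n_samples=("sample_id", "size"),
                   n_failing=("passes", lambda s: int((~s).sum())))
              .reset_index())
    by_cat["failure_pct"] = round(
        100 * by_cat["n_failing"] / by_cat["n_samples"], 2)

    kept = merged[merged["quality_category"] != "poor"]

    def rate(sub):
        return (round(100 * float((~sub["passes"]).mean()), 2)
                if len(sub) else None)

    counterfactual = {
        "overall_failure_pct": rate(kept),
        "observed_failure_pct": rate(merged),
        "n_excluded_poor": int((merged["quality_category"] == "poor").sum()),
        "by_source": {src: rate(sub)
                      for src, sub in kept.groupby("source_material")},
    }
    return by_cat, counterfactual
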