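"""Per-sample completion and heterozygosity QC.

Call rates are computed against input-type-specific denominators: probes
that never yield a genotype in any sample are removed from both
denominators, and probes failing across every wgaDNA sample are
additionally removed from the wgaDNA denominator, so a sample is judged
only on probes that *could* have worked for its input type.  A sample
fails QC when its call rate is below 95% (a rate of exactly 0.95
passes).  Heterozygosity is the fraction of called autosomal genotypes
that are AB; outliers are flagged with Tukey fences (the fence
multiplier is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import NC, AB
from . import locus_qc

CALL_RATE_THRESHOLD = 0.95
DEFAULT_FENCE_K = 3.0
DEFAULT_PLATE_ALPHA = 1e-4


@dataclass
class DenominatorResult:
    n_probes_total: int
    n_failed_all: int
    n_failed_wga_only: int

    @property
    def denominators(self) -> dict:
        return denominators_from_failure_counts(
            self.n_probes_total, self.n_failed_all, self.n_failed_wga_only)


def denominators_from_failure_counts(n_probes_total: int, n_failed_all: int,
                                     n_failed_wga_only: int) -> dict:
    """Input-type denominators from probe-failure counts.

    gDNA keeps every probe that did not fail completely; wgaDNA
    additionally loses the probes that failed across all wgaDNA samples.
    """
    gdna = n_probes_total - n_failed_all
    return {"gDNA": gdna, "wgaDNA": gdna - n_failed_wga_only}


def compute_denominators(calls: pd.DataFrame,
                         cohort: pd.DataFrame) -> DenominatorResult:
    """Classify probe failures and derive per-input-type denominators."""
    if len(calls) == 0:
        raise ValueError("empty call table")
    for itype in ("gDNA", "wgaDNA"):
        if not (cohort["input_type"] == itype).any():
            raise ValueError(f"no {itype} samples in cohort")
    classes = locus_qc.classify_probe_failures(calls, cohort)
    counts = classes["failure_class"].value_counts()
    return DenominatorResult(
        n_probes_total=len(classes),
        n_failed_all=int(counts.get("failed_all", 0)),
        n_failed_wga_only=int(counts.get("failed_wga_only", 0)),
    )


def compute_call_rates(calls: pd.DataFrame, denominators: dict,
                       cohort: pd.DataFrame,
                       threshold: float = CALL_RATE_THRESHOLD) -> pd.DataFrame:
    """Per-sample call rate against the input-type denominator.

    Returns one row per sample: ``n_informative``, ``n_denominator``,
    ``call_rate`` and ``passes`` (rate >= threshold passes; "less than
    95%" fails).
    """
    for itype, d in denominators.items():
        if d <= 0:
            raise ValueError(f"non-positive denominator for {itype}")
    informative = (calls.loc[calls["genotype"] != NC]
                   .groupby("sample_id", observed=True).size())
    present = calls.groupby("sample_id", observed=True).size()
    out = cohort[["sample_id", "individual_id", "input_type",
                  "source_material"]].copy()
    missing = set(out["sample_id"]) - set(present.index)
    if missing:
        raise ValueError(f"samples with zero probes in call table: "
                         f"{sorted(missing)[:5]}")
    out["n_informative"] = out["sample_id"].map(informative).fillna(0).astype(int)
    out["n_denominator"] = out["input_type"].map(denominators).astype(int)
    out["call_rate"] = out["n_informative"] / out["n_denominator"]
    out["passes"] = out["call_rate"] >= threshold
    return out


def detect_systematic_failures(call_rates: pd.DataFrame, cohort: pd.DataFrame,
                               plate_alpha: float = DEFAULT_PLATE_ALPHA):
    """Chip- and plate-level systematic failure detection.

    Chips where all 4 samples fail the call-rate threshold are marked
    ``exclude``; chips with 3 of 4 failing are ``flag`` (retained —
    suggestive of a processing problem but not confirmable).  Plates are
    flagged when their failing fraction exceeds the cohort-wide rate by
    a binomial tail test at ``plate_alpha``; plate exclusion is left to
    manual review.

    Returns ``(chip_reports, plate_reports)``.
    """
    cr = call_rates.merge(cohort[["sample_id", "chip_id", "plate_id"]],
                          on="sample_id")
    chip = (cr.groupby("chip_id")
              .agg(n_samples=("sample_id", "size"),
                   n_failing=("passes", lambda s: int((~s).sum())))
              .reset_index())
    chip["action"] = "none"
    chip.loc[(chip["n_failing"] == chip["n_samples"])
             & (chip["n_samples"] == 4), "action"] = "exclude"
    chip.loc[(chip["n_failing"] == 3) & (chip["n_samples"] == 4),
             "action"] = "flag"
    chip_reports = chip[chip["action"] != "none"].reset_index(drop=True)

    p0 = (~cr["passes"]).mean()
    plate = (cr.groupby("plate_id")
               .agg(n_samples=("sample_id", "size"),
                    n_failing=("passes", lambda s: int((~s).sum())))
               .reset_index())
    if p0 > 0:
        plate["p_value"] = stats.binom.sf(plate["n_failing"] - 1,
                                          plate["n_samples"], p0)
    else:
        plate["p_value"] = np.where(plate["n_failing"] > 0, 0.0, 1.0)
    plate["action"] = np.where(plate["p_value"] < plate_alpha, "flag", "none")
    plate_reports = plate[plate["action"] == "flag"].reset_index(drop=True)
    return chip_reports, plate_reports


def compute_heterozygosity(calls: pd.DataFrame, manifest: pd.DataFrame,
                           autosomes_only: bool = True) -> pd.DataFrame:
    """Per-sample heterozygosity over called genotypes.

    By default sex chromosomes (named ``chrX``/``chrY``) are excluded so
    hemizygous males do not depress the rate.
    """
    use = calls
    if autosomes_only:
        sex_probes = set(
            manifest.loc[manifest["chromosome"].isin(["chrX", "chrY", "X", "Y"]),
                         "probe_id"])
        if sex_probes:
            use = calls[~calls["probe_id"].isin(sex_probes)]
    called = use[use["genotype"] != NC]
    grp = called.groupby("sample_id", observed=True)["genotype"]
    out = pd.DataFrame({
        "n_het": grp.apply(lambda g: int((g == AB).sum())),
        "n_called": grp.size(),
    }).reset_index()
    zero = set(use["sample_id"].unique()) - set(out["sample_id"])
    if zero or (out["n_called"] == 0).any():
        bad = sorted(zero) + list(out.loc[out["n_called"] == 0, "sample_id"])
        raise ValueError(f"samples with zero called genotypes: {bad[:5]}")
    out["het_rate"] = out["n_het"] / out["n_called"]
    out["is_outlier"] = False
    return out


def flag_het_outliers(het_results: pd.DataFrame,
                      k: float = DEFAULT_FENCE_K) -> pd.DataFrame:
    """Tukey-fence outlier flag: outside [Q1 - k*IQR, Q3 + k*IQR]."""
    if len(het_results) < 5:
        raise ValueError("need at least 5 samples to flag outliers")
    out = het_results.copy()
    q1, q3 = out["het_rate"].quantile([0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out["is_outlier"] = (out["het_rate"] < lo) | (out["het_rate"] > hi)
    return out


def failure_rate_report(call_rates: pd.DataFrame,
                        cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Failure counts and percentages stratified by input type x source.

    Emits one row per stratum, one per input type overall, and one
    cohort-wide row; ``failure_pct`` is rounded to 2 decimals for
    display while ``failure_rate`` keeps full precision.
    """
    cr = call_rates
    if "source_material" not in cr.columns:
        cr = cr.merge(cohort[["sample_id", "input_type", "source_material"]],
                      on="sample_id")
    rows = []

    def add(itype, source, sub):
        n = len(sub)
        k = int((~sub["passes"]).sum())
        rate = k / n if n else np.nan
        rows.append((itype, source, n, k, rate, round(100 * rate, 2)))

    for itype, sub_t in cr.groupby("input_type"):
        for source, sub in sub_t.groupby("source_material"):
            add(itype, source, sub)
        add(itype, "all", sub_t)
    add("all", "all", cr)
    return pd.DataFrame(rows, columns=["input_type", "source_material",
                                       "n_samples", "n_failing",
                                       "failure_rate", "failure_pct"])


def select_repeats(call_rates: pd.DataFrame,
                   het_results: pd.DataFrame) -> pd.DataFrame:
    """Samples to repeat: failing call rate, or passing with outlier het.

    A sample matching both criteria appears once, tagged with both
    reasons.
    """
    merged = call_rates.merge(
        het_results[["sample_id", "het_rate", "is_outlier"]],
        on="sample_id", how="left")
    merged["is_outlier"] = merged["is_outlier"].fillna(False).astype(bool)
    reasons = {}
    for row in merged.itertuples(index=False):
        r = []
        if not row.passes:
            r.append("low_call_rate")
        if row.is_outlier:
            r.append("het_outlier")
        if r:
            reasons[row.sample_id] = r
    return pd.DataFrame(
        [(s, ";".join(r)) for s, r in reasons.items()],
        columns=["sample_id", "reasons"])
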