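"""Replicate-pair and duplicate-locus genotype concordance.

Two independent reproducibility surfaces:

* **between samples** — all unordered within-individual pairs, typed as
  gDNA-gDNA / gDNA-wgaDNA / wgaDNA-wgaDNA, compared over probes where
  both members yield a genotype (mismatch is class-level AA/AB/BB; a
  no-call in either member removes the probe from the denominator);
* **within loci** — for loci assayed by more than one probe, the
  fraction of samples whose duplicate probes all agree, evaluated
  separately per input type and classified at a 99% threshold, with
  minor-allele-frequency strata and an r2 of concordance against MAF.

MAF is computed on one sample per individual (gDNA preferred, then
highest call rate) so replicate individuals are not double-counted.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .genotype_io import NC, AB, BB

PAIR_TYPES = {("gDNA", "gDNA"): "gDNA-gDNA",
              ("gDNA", "wgaDNA"): "gDNA-wgaDNA",
              ("wgaDNA", "gDNA"): "gDNA-wgaDNA",
              ("wgaDNA", "wgaDNA"): "wgaDNA-wgaDNA"}

DEFAULT_DUPLICATE_THRESHOLD = 0.99
DEFAULT_OUTLIER_FLOOR = 0.995


def genotype_matrix(calls: pd.DataFrame):
    """Pivot a long call table to a (probe x sample) int8 genotype matrix.

    Returns ``(matrix, probe_index, sample_index)``; absent
    (sample, probe) combinations are NC.
    """
    samples = pd.Index(calls["sample_id"].unique())
    probes = pd.Index(calls["probe_id"].unique())
    s_code = samples.get_indexer(calls["sample_id"])
    p_code = probes.get_indexer(calls["probe_id"])
    mat = np.full((len(probes), len(samples)), NC, dtype=np.int8)
    mat[p_code, s_code] = calls["genotype"].to_numpy()
    return mat, probes, samples


def pair_replicates(cohort: pd.DataFrame,
                    call_rates: pd.DataFrame | None = None) -> pd.DataFrame:
    """All unordered within-individual sample pairs, typed.

    When ``call_rates`` is given, pairs where either member fails the
    call-rate threshold are marked excluded (``included=False``) but
    kept in the table.
    """
    passes = (dict(zip(call_rates["sample_id"], call_rates["passes"]))
              if call_rates is not None else None)
    rows = []
    for ind, grp in cohort.groupby("individual_id"):
        recs = list(grp[["sample_id", "input_type"]].itertuples(index=False))
        for a, b in itertools.combinations(recs, 2):
            ptype = PAIR_TYPES[(a.input_type, b.input_type)]
            inc = True
            if passes is not None:
                inc = bool(passes.get(a.sample_id, False)
                           and passes.get(b.sample_id, False))
            rows.append((ind, a.sample_id, b.sample_id, ptype, inc))
    return pd.DataFrame(rows, columns=["individual_id", "sample_a", "sample_b",
                                       "pair_type", "included"])


def compute_pair_concordance(calls: pd.DataFrame, pairs: pd.DataFrame,
                             matrix=None) -> pd.DataFrame:
    """Concordance for every pair over probes called in both members.

    ``matrix`` may carry a precomputed :func:`genotype_matrix` result to
    amortise the pivot across many pairs.
    """
    mat, probes, samples = matrix if matrix is not None else genotype_matrix(calls)
    n_both = np.empty(len(pairs), dtype=np.int64)
    n_conc = np.empty(len(pairs), dtype=np.int64)
    for i, row in enumerate(pairs.itertuples(index=False)):
        ia = samples.get_loc(row.sample_a)
        ib = samples.get_loc(row.sample_b)
        ga, gb = mat[:, ia], mat[:, ib]
        both = (ga != NC) & (gb != NC)
        n_both[i] = int(both.sum())
        if n_both[i] == 0:
            raise ValueError(
                f"no co-called probes for pair {row.sample_a}/{row.sample_b}")
        n_conc[i] = int((ga[both] == gb[both]).sum())
    out = pairs.copy()
    out["n_both_called"] = n_both
    out["n_concordant"] = n_conc
    out["concordance"] = n_conc / n_both
    return out


def summarize_concordance(pairs: pd.DataFrame,
                          outlier_floor: float = DEFAULT_OUTLIER_FLOOR):
    """Per-pair-type mean/min over included pairs, plus low outliers.

    Returns ``(summary, outliers)``.
    """
    inc = pairs[pairs.get("included", pd.Series(True, index=pairs.index))]
    if len(inc) == 0:
        raise ValueError("no included pairs")
    summary = (inc.groupby("pair_type")["concordance"]
                  .agg(n_pairs="size", mean="mean", min="min")
                  .reset_index())
    outliers = inc[inc["concordance"] < outlier_floor][
        ["individual_id", "sample_a", "sample_b", "pair_type", "concordance"]]
    return summary, outliers.reset_index(drop=True)


def _preferred_samples(cohort: pd.DataFrame,
                       call_rates: pd.DataFrame | None) -> list:
    """One sample per individual: gDNA preferred, then highest call rate."""
    rates = (dict(zip(call_rates["sample_id"], call_rates["call_rate"]))
             if call_rates is not None else {})
    chosen = []
    for _, grp in cohort.groupby("individual_id"):
        grp = grp.copy()
        grp["_is_g"] = (grp["input_type"] == "gDNA").astype(int)
        grp["_rate"] = grp["sample_id"].map(rates).fillna(0.0)
        grp = grp.sort_values(["_is_g", "_rate", "sample_id"],
                              ascending=[False, False, True])
        chosen.append(grp.iloc[0]["sample_id"])
    return chosen


def compute_maf(calls: pd.DataFrame, cohort: pd.DataFrame,
                manifest: pd.DataFrame,
                call_rates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-locus minor allele frequency over one sample per individual.

    The B-allele frequency is counted from genotype classes
    (``f_B = (n_AB + 2 n_BB) / 2 n_called``) on each locus's first
    probe, then folded: ``maf = min(f, 1 - f)``.
    """
    if cohort["individual_id"].nunique() < 1:
        raise ValueError("need at least one individual")
    keep = set(_preferred_samples(cohort, call_rates))
    sub = calls[calls["sample_id"].isin(keep) & (calls["genotype"] != NC)]
    first_probe = manifest.drop_duplicates("locus_id")[["probe_id", "locus_id"]]
    sub = sub.merge(first_probe, on="probe_id")
    g = sub["genotype"].to_numpy()
    sub = pd.DataFrame({"locus_id": sub["locus_id"].to_numpy(),
                        "b_alleles": (g == AB) + 2 * (g == BB),
                        "one": 1})
    agg = sub.groupby("locus_id").agg(n_b=("b_alleles", "sum"),
                                      n_individuals=("one", "sum")).reset_index()
    f = agg["n_b"] / (2 * agg["n_individuals"])
    agg["f_b"] = f
    agg["maf"] = np.minimum(f, 1 - f)
    return agg[["locus_id", "maf", "f_b", "n_individuals"]]


def duplicate_locus_concordance(calls: pd.DataFrame, manifest: pd.DataFrame,
                                maf_table: pd.DataFrame,
                                cohort: pd.DataFrame,
                                threshold: float = DEFAULT_DUPLICATE_THRESHOLD,
                                matrix=None):
    """Within-locus agreement of duplicate probes, per input type.

    For each locus with >= 2 probes and each input type, concordance is
    the fraction of samples — among those where *all* duplicate probes
    are called — whose probe calls all agree (within-sample agreement
    aggregated across samples).  Loci evaluable in both input types are
    classified at ``threshold`` into both_high / both_low /
    low_gdna_only / low_wga_only.

    Returns ``(per_locus, summary)`` where ``summary`` holds class
    percentages, MAF strata counts and the r2 of concordance vs MAF.
    """
    dup_counts = manifest["locus_id"].value_counts()
    dup_loci = dup_counts[dup_counts >= 2].index
    if len(dup_loci) == 0:
        raise ValueError("no duplicate loci in manifest")
    mat, probes, samples = matrix if matrix is not None else genotype_matrix(calls)
    is_wga = samples.isin(
        set(cohort.loc[cohort["input_type"] == "wgaDNA", "sample_id"]))
    maf_map = dict(zip(maf_table["locus_id"], maf_table["maf"]))

    rows = []
    skipped = []
    for locus in dup_loci:
        pids = manifest.loc[manifest["locus_id"] == locus, "probe_id"]
        idx = probes.get_indexer(pids)
        if (idx < 0).any() or len(idx) < 2:
            skipped.append(locus)
            continue
        sub = mat[idx]                       # (k probes, n samples)
        all_called = (sub != NC).all(axis=0)
        agree = (sub == sub[0]).all(axis=0)
        res = {}
        for label, mask in (("gdna", ~is_wga), ("wga", is_wga)):
            ok = all_called & mask
            res[label] = (float((agree & ok).sum() / ok.sum())
                          if ok.sum() else np.nan)
        rows.append((locus, len(idx), res["gdna"], res["wga"],
                     maf_map.get(locus, np.nan)))

    per_locus = pd.DataFrame(rows, columns=[
        "locus_id", "n_probes", "concordance_gdna", "concordance_wga", "maf"])

    both = per_locus.dropna(subset=["concordance_gdna", "concordance_wga"])
    lo_g = both["concordance_gdna"] <= threshold
    lo_w = both["concordance_wga"] <= threshold
    cls = np.select(
        [lo_g & lo_w, lo_g & ~lo_w, ~lo_g & lo_w],
        ["both_low", "low_gdna_only", "low_wga_only"], default="both_high")
    per_locus = per_locus.merge(
        pd.DataFrame({"locus_id": both["locus_id"], "class": cls}),
        on="locus_id", how="left")

    def r2(sub, col):
        v = sub.dropna(subset=[col, "maf"])
        if len(v) < 3 or v[col].std() == 0 or v["maf"].std() == 0:
            return None
        return float(np.corrcoef(v[col], v["maf"])[0, 1] ** 2)

    n_eval = len(both)
    summary = {
        "n_duplicate_loci": len(per_locus) + len(skipped),
        "n_evaluated_both_inputs": n_eval,
        "skipped_loci": skipped,
        "class_pct": {c: round(100 * (cls == c).mean(), 4) if n_eval else None
                      for c in ("both_high", "both_low",
                                "low_gdna_only", "low_wga_only")},
        "n_maf_le_5pct": int((both["maf"] <= 0.05).sum()),
        "n_maf_le_1pct": int((both["maf"] <= 0.01).sum()),
        "r2_concordance_maf_gdna": r2(both, "concordance_gdna"),
        "r2_concordance_maf_wga": r2(both, "concordance_wga"),
    }
    return per_locus, summary
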