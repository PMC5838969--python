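"""Probe/locus failure classification and positional failure maps.

Probes are classified as ``ok``, ``failed_all`` (no genotype from any
sample) or ``failed_wga_only`` (no genotype from any wgaDNA sample but
at least one gDNA call).  Probe classes are collapsed to unique loci —
a locus counts as failed only when *all* of its probes are failed — and
the failed loci are binned into fixed 50-kb windows per chromosome,
anchored at genome position 1, to map regional artifacts such as
subtelomeric under-amplification of whole-genome-amplified DNA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import NC

DEFAULT_WINDOW_SIZE = 50_000


def classify_probe_failures(calls: pd.DataFrame,
                            cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-probe failure class from called-genotype counts by input type."""
    for itype in ("gDNA", "wgaDNA"):
        if not (cohort["input_type"] == itype).any():
            raise ValueError(f"no {itype} samples present")
    wga = set(cohort.loc[cohort["input_type"] == "wgaDNA", "sample_id"])
    called = calls[calls["genotype"] != NC]
    is_wga = called["sample_id"].isin(wga).to_numpy()
    per_probe = (pd.DataFrame({"probe_id": called["probe_id"].to_numpy(),
                               "wga": is_wga})
                 .groupby("probe_id", observed=True)["wga"]
                 .agg(n_called_wga="sum", n_called="size"))
    all_probes = calls["probe_id"].unique()
    out = pd.DataFrame({"probe_id": pd.Series(all_probes, dtype=object)})
    out = out.merge(per_probe.reset_index(), on="probe_id", how="left")
    out[["n_called_wga", "n_called"]] = (
        out[["n_called_wga", "n_called"]].fillna(0).astype(int))
    out["n_called_gdna"] = out["n_called"] - out["n_called_wga"]
    cls = np.full(len(out), "ok", dtype=object)
    cls[(out["n_called"] == 0).to_numpy()] = "failed_all"
    cls[((out["n_called_wga"] == 0) & (out["n_called_gdna"] > 0)).to_numpy()] = \
        "failed_wga_only"
    out["failure_class"] = cls
    return out[["probe_id", "n_called_gdna", "n_called_wga", "failure_class"]]


def collapse_to_loci(classes: pd.DataFrame,
                     manifest: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe failure classes to unique annotated loci.

    A locus is ``failed_all`` only when every probe assaying it yielded
    no genotype anywhere, and ``failed_wga_only`` when every probe
    yielded nothing in wgaDNA but the locus was called in gDNA — the
    most conservative reading of locus failure.
    """
    missing = set(classes["probe_id"]) - set(manifest["probe_id"])
    if missing:
        raise ValueError(f"probes absent from manifest: {sorted(missing)[:5]}")
    merged = classes.merge(manifest[["probe_id", "locus_id"]], on="probe_id")
    grp = merged.groupby("locus_id")
    agg = grp.agg(n_probes=("probe_id", "size"),
                  called_gdna=("n_called_gdna", "sum"),
                  called_wga=("n_called_wga", "sum")).reset_index()
    cls = np.full(len(agg), "ok", dtype=object)
    none_called = (agg["called_gdna"] == 0) & (agg["called_wga"] == 0)
    cls[none_called.to_numpy()] = "failed_all"
    cls[((agg["called_wga"] == 0) & (agg["called_gdna"] > 0)).to_numpy()] = \
        "failed_wga_only"
    agg["failure_class"] = cls
    return agg


def window_failure_counts(locus_failures: pd.DataFrame, manifest: pd.DataFrame,
                          window_size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Bin loci into genome-anchored half-open windows and count failures.

    Window index is ``floor((position - 1) / window_size)`` so positions
    1..window_size share window 1 (1-based ``window_start``); every
    locus lands in exactly one window.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    loci = manifest.drop_duplicates("locus_id")[
        ["locus_id", "chromosome", "position", "gc_fraction"]]
    merged = loci.merge(
        locus_failures[["locus_id", "failure_class"]], on="locus_id", how="left")
    merged["failure_class"] = merged["failure_class"].fillna("ok")
    merged["window_start"] = (
        (merged["position"] - 1) // window_size * window_size + 1)
    grp = merged.groupby(["chromosome", "window_start"])
    out = grp.agg(
        n_loci_total=("locus_id", "size"),
        n_failed_all=("failure_class", lambda s: int((s == "failed_all").sum())),
        n_failed_wga_only=("failure_class",
                           lambda s: int((s == "failed_wga_only").sum())),
        gc_mean=("gc_fraction", "mean"),
    ).reset_index()
    out["is_subtelomeric"] = False
    key = out["chromosome"].astype(str).str.removeprefix("chr")
    out["_k"] = pd.to_numeric(key, errors="coerce").fillna(1e9)
    out = (out.sort_values(["_k", "chromosome", "window_start"])
              .drop(columns="_k").reset_index(drop=True))
    return out


def flag_subtelomeric(windows: pd.DataFrame, k_terminal: int) -> pd.DataFrame:
    """Flag the terminal ``k_terminal`` covered windows at each chromosome end."""
    out = windows.copy()
    out["is_subtelomeric"] = False
    if k_terminal <= 0:
        return out
    for _, grp in out.groupby("chromosome", sort=False):
        idx = grp.sort_values("window_start").index
        take = list(idx[:k_terminal]) + list(idx[-k_terminal:])
        out.loc[take, "is_subtelomeric"] = True
    return out


def gc_association(windows: pd.DataFrame, which: str = "n_failed_wga_only",
                   n_boot: int = 1000, seed: int = 0) -> dict:
    """Correlation between window failure fraction and window GC content.

    Reports Pearson and Spearman coefficients and a bootstrap percentile
    CI for the Pearson r.  With zero variance in either variable the
    correlation is undefined and reported as such rather than NaN-ing
    silently.
    """
    if len(windows) < 10:
        raise ValueError("need at least 10 windows")
    frac = (windows[which] / windows["n_loci_total"]).to_numpy(dtype=float)
    gc = windows["gc_mean"].to_numpy(dtype=float)
    if np.ptp(frac) == 0 or np.ptp(gc) == 0:
        return {"defined": False, "pearson_r": None, "spearman_rho": None,
                "ci_low": None, "ci_high": None, "n_windows": len(windows)}
    pearson = stats.pearsonr(frac, gc)
    spearman = stats.spearmanr(frac, gc)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(frac)
    for _ in range(n_boot):
        i = rng.integers(0, n, n)
        if np.ptp(frac[i]) == 0 or np.ptp(gc[i]) == 0:
            continue
        boots.append(stats.pearsonr(frac[i], gc[i]).statistic)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return {"defined": True,
            "pearson_r": float(pearson.statistic),
            "pearson_p": float(pearson.pvalue),
            "spearman_rho": float(spearman.statistic),
            "ci_low": float(lo), "ci_high": float(hi),
            "n_windows": len(windows)}
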