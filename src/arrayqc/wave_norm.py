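"""LRR/BAF computation and GC/CpG wave renormalization of LRR.

LRR and BAF are derived from raw two-channel intensities relative to
per-probe genotype cluster positions: with normalized angle
``theta = (2/pi) atan2(y, x)`` and total intensity ``R = x + y``, LRR is
``log2(R / R_expected)`` where the expected intensity interpolates
linearly between the flanking cluster centroids, and BAF interpolates
theta piecewise-linearly through the AA/AB/BB centroids (clamped to
[0, 1]).

Long-range "GC waves" — undulation of LRR correlated with local GC
content, aggravated by input quantity differences — obscure copy-number
signal.  The renormalization here is deliberately simple and fully
specified: per-sample quantile normalization of total intensity to a
cohort reference distribution, then a per-sample least-squares fit of
LRR on centred polynomial GC and CpG-density terms (default degree 2)
with a per-chip multiplicative rescaling factor, subtracted from the
raw LRR.  Genotype calls are never modified by normalization; BAF is
not wave-corrected (the correction demonstrably barely moves BAF
dispersion) but can be re-estimated from normalized intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import NC

DEFAULT_DEGREE = 2


@dataclass
class ClusterModel:
    """Per-probe genotype cluster centroids in (theta, R) space."""
    probe_ids: np.ndarray
    theta: np.ndarray   # (P, 3) increasing: AA, AB, BB
    r: np.ndarray       # (P, 3) expected intensity at each centroid

    def __post_init__(self):
        if not (np.all(self.theta[:, 0] < self.theta[:, 1])
                and np.all(self.theta[:, 1] < self.theta[:, 2])):
            raise ValueError("cluster thetas must be strictly increasing")

    @classmethod
    def uniform(cls, probe_ids, thetas=(0.1, 0.5, 0.9), r=2.0):
        p = len(probe_ids)
        return cls(np.asarray(probe_ids),
                   np.tile(np.asarray(thetas, float), (p, 1)),
                   np.full((p, 3), float(r)))


@dataclass
class WaveModel:
    """Fitted wave-correction model.

    ``coefficients`` has one row per sample (intercept + polynomial
    terms); ``chip_rescale`` maps chip id to a positive multiplicative
    intensity factor, ``2 ** (mean fitted intercept of the chip)``.
    """
    coefficients: pd.DataFrame
    chip_rescale: dict
    residual_sd: pd.Series
    degree: int
    term_names: list
    gc_center: float
    cpg_center: float


def compute_lrr_baf(x_raw, y_raw, probe_ids, cluster: ClusterModel):
    """LRR and BAF from raw intensities and cluster positions.

    ``x_raw``/``y_raw`` may be 1-D (one value per probe) or 2-D
    (samples x probes).  Probes with ``x = y = 0`` give NaN for both
    quantities (undefined rather than -inf).
    """
    idx = pd.Index(cluster.probe_ids).get_indexer(probe_ids)
    if (idx < 0).any():
        raise ValueError("cluster model does not cover every probe")
    th = cluster.theta[idx]
    rr = cluster.r[idx]
    x = np.asarray(x_raw, dtype=float)
    y = np.asarray(y_raw, dtype=float)
    theta = (2 / np.pi) * np.arctan2(y, x)
    r = x + y

    t_aa, t_ab, t_bb = th[..., 0], th[..., 1], th[..., 2]
    r_aa, r_ab, r_bb = rr[..., 0], rr[..., 1], rr[..., 2]

    # piecewise-linear interpolation of expected R and of BAF in theta
    lo = theta <= t_ab
    frac_lo = (theta - t_aa) / (t_ab - t_aa)
    frac_hi = (theta - t_ab) / (t_bb - t_ab)
    r_exp = np.where(lo, r_aa + np.clip(frac_lo, 0, 1) * (r_ab - r_aa),
                     r_ab + np.clip(frac_hi, 0, 1) * (r_bb - r_ab))
    baf = np.where(lo, 0.5 * frac_lo, 0.5 + 0.5 * frac_hi)
    baf = np.clip(baf, 0.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        lrr = np.log2(r / r_exp)
    undefined = r == 0
    lrr = np.where(undefined, np.nan, lrr)
    baf = np.where(undefined, np.nan, baf)
    return lrr, baf


def quantile_normalize(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map a vector onto the order statistics of a reference distribution.

    The output's sorted values equal the sorted reference exactly; tied
    input values all receive the mean of the reference values at the
    tied positions, so the map is well defined and idempotent against
    its own output.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if values.shape != reference.shape:
        raise ValueError("reference length must match vector length")
    order = np.argsort(values, kind="stable")
    ref_sorted = np.sort(reference)
    sorted_vals = values[order]
    # group boundaries of runs of equal values
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    sums = np.add.reduceat(ref_sorted, starts)
    lengths = np.diff(np.concatenate([starts, [len(values)]]))
    group_means = sums / lengths
    assigned = np.repeat(group_means, lengths)
    out = np.empty_like(values)
    out[order] = assigned
    return out


def _design(gc, cpg, degree, gc_center, cpg_center):
    cols = [np.ones_like(gc)]
    names = ["intercept"]
    for d in range(1, degree + 1):
        cols.append((gc - gc_center) ** d)
        names.append(f"gc^{d}")
    for d in range(1, degree + 1):
        cols.append((cpg - cpg_center) ** d)
        names.append(f"cpg^{d}")
    return np.column_stack(cols), names


def fit_wave_model(lrr: np.ndarray, manifest: pd.DataFrame,
                   cohort: pd.DataFrame, degree: int = DEFAULT_DEGREE,
                   sample_ids=None) -> WaveModel:
    """Per-sample least-squares wave fit with per-chip rescaling.

    ``lrr`` is (samples x probes) aligned with ``cohort`` rows and
    manifest order.  Each sample's LRR is regressed on centred
    ``gc, gc^2, ..., gc^degree`` and matching CpG terms; a rank-deficient
    design (e.g. constant GC) falls back to a lower degree with a
    warning.  The chip rescaling factor is ``2 ** (chip mean intercept)``
    — a constant chip-wide intensity offset is absorbed entirely by it.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    lrr = np.atleast_2d(np.asarray(lrr, dtype=float))
    if lrr.shape[1] < 100:
        raise ValueError("need at least 100 probes per sample")
    gc = manifest["gc_fraction"].to_numpy(dtype=float)
    cpg = manifest["cpg_density"].to_numpy(dtype=float)
    gc_c, cpg_c = float(gc.mean()), float(cpg.mean())

    deg = degree
    while deg >= 1:
        X, names = _design(gc, cpg, deg, gc_c, cpg_c)
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        deg -= 1
        warnings.warn(f"rank-deficient wave design; falling back to degree {deg}")
    else:
        X, names = np.ones((len(gc), 1)), ["intercept"]

    coef, *_ = np.linalg.lstsq(X, lrr.T, rcond=None)
    fitted = X @ coef
    resid = lrr.T - fitted
    sample_ids = (list(sample_ids) if sample_ids is not None
                  else list(cohort["sample_id"]))
    coef_df = pd.DataFrame(coef.T, columns=names, index=sample_ids)
    residual_sd = pd.Series(resid.std(axis=0, ddof=1), index=sample_ids)

    chip_of = dict(zip(cohort["sample_id"], cohort["chip_id"]))
    intercepts = coef_df["intercept"]
    chip_rescale = {}
    groups: dict[str, list] = {}
    for s in sample_ids:
        groups.setdefault(chip_of.get(s, "chip0"), []).append(s)
    for chip, members in groups.items():
        chip_rescale[chip] = float(2.0 ** intercepts.loc[members].mean())
    return WaveModel(coef_df, chip_rescale, residual_sd, deg, names, gc_c, cpg_c)


def correct_waves(lrr: np.ndarray, model: WaveModel,
                  manifest: pd.DataFrame) -> np.ndarray:
    """Subtract the fitted wave term (incl. intercept) from each sample.

    Least squares makes the adjusted per-sample mean ~0 and strictly
    reduces the per-sample variance whenever the fit explains anything.
    Genotype calls are untouched by construction — the function only
    sees LRR.
    """
    lrr = np.atleast_2d(np.asarray(lrr, dtype=float))
    gc = manifest["gc_fraction"].to_numpy(dtype=float)
    cpg = manifest["cpg_density"].to_numpy(dtype=float)
    X, _ = _design(gc, cpg, model.degree, model.gc_center, model.cpg_center)
    fitted = X @ model.coefficients.to_numpy().T
    return lrr - fitted.T


def sd_report(lrr_raw: np.ndarray, lrr_adjusted: np.ndarray,
              baf: np.ndarray, genotypes: np.ndarray,
              sample_ids) -> pd.DataFrame:
    """Per-sample dispersion before/after correction.

    BAF sd is computed genotype-conditionally — deviations from the
    0 / 0.5 / 1 cluster center of each called genotype — so the
    three-cluster structure does not dominate the statistic.
    """
    lrr_raw = np.atleast_2d(lrr_raw)
    lrr_adjusted = np.atleast_2d(lrr_adjusted)
    baf = np.atleast_2d(baf)
    genotypes = np.atleast_2d(genotypes)
    centers = np.array([0.0, 0.5, 1.0])
    rows = []
    for i, s in enumerate(sample_ids):
        g = genotypes[i]
        called = g != NC
        dev = baf[i, called] - centers[g[called]]
        rows.append((s,
                     float(np.nanstd(lrr_raw[i], ddof=1)),
                     float(np.nanstd(lrr_adjusted[i], ddof=1)),
                     float(np.std(dev, ddof=1)) if called.sum() > 1 else np.nan))
    return pd.DataFrame(rows, columns=["sample_id", "lrr_sd_raw",
                                       "lrr_sd_adjusted", "baf_sd"])
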