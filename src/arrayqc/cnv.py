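"""Copy-number and allelic-imbalance detection via circular binary segmentation.

Both the LRR track (dosage) and the mirrored-BAF track
(``mbaf = max(BAF, 1 - BAF)`` over informative probes — heterozygous
calls, plus probes with BAF inside an open interval around the
homozygous clusters so mosaic hets are retained) are segmented with CBS:
recursive search for the arc whose t-like statistic against its
complement is maximal, accepted when a permutation test beats ``alpha``,
with segments shorter than ``min_probes`` (default 20, to limit false
discovery) merged into their closer neighbor.

Breakpoints from the two tracks are then combined: atomic intervals
between the union of boundaries are classified from their mean LRR and
mean mBAF (gain / loss / copy-neutral LOH / mosaic CN-LOH, thresholds
config-exposed); intervals with conflicting evidence are emitted
flagged for manual review rather than silently dropped.  For mosaic
CN-LOH the cell fraction is ``2 * (mbaf - 0.5)`` — exact for
copy-neutral events only, so gains and losses carry no fraction.

Matched-pair concordance counts a reference (gDNA) event as a true
positive when the test (wgaDNA) sample has an event of the same class
on the same chromosome with reciprocal overlap >= 50%; unmatched
reference events are false negatives and unmatched test events false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import NC, AB

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_MIN_PROBES = 20
DEFAULT_DELTA = 0.15
DEFAULT_OVERLAP = 0.5
DEFAULT_SD_GATE = 0.30

_PERM_CHUNK = 64


# ---------------------------------------------------------------------------
# Mirrored BAF
# ---------------------------------------------------------------------------

def mirrored_baf(calls: pd.DataFrame, manifest: pd.DataFrame,
                 delta: float = DEFAULT_DELTA) -> pd.DataFrame:
    """Ordered (position, mbaf) series of informative probes per sample.

    Informative probes are heterozygous calls plus any probe whose BAF
    lies strictly inside ``(delta, 1 - delta)``; the latter keeps
    partially shifted hets in mosaic regions where the genotype caller
    already reports a homozygote.
    """
    pos = manifest.set_index("probe_id")[["chromosome", "position"]]
    baf = calls["baf"].to_numpy(dtype=float)
    keep = (calls["genotype"].to_numpy() == AB) | ((baf > delta)
                                                   & (baf < 1 - delta))
    sub = calls.loc[keep, ["sample_id", "probe_id", "baf"]].copy()
    sub["mbaf"] = np.maximum(sub["baf"], 1 - sub["baf"])
    sub = sub.join(pos, on="probe_id")
    key = sub["chromosome"].astype(str).str.removeprefix("chr")
    sub["_k"] = pd.to_numeric(key, errors="coerce").fillna(1e9)
    sub = (sub.sort_values(["sample_id", "_k", "position"])
              .drop(columns="_k").reset_index(drop=True))
    return sub[["sample_id", "probe_id", "chromosome", "position", "mbaf"]]


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def _max_arc_t(x: np.ndarray):
    """Maximal |t| over all arcs [i, j) vs complement; first max wins.

    Enumerating contiguous arcs covers circular arcs too: a wrapped arc
    is the complement of a contiguous one and shares its |t|.
    """
    n = len(x)
    s = float(np.std(x, ddof=1))
    if s == 0:
        return 0.0, 0, n
    S = np.concatenate([[0.0], np.cumsum(x)])
    tot = S[-1]
    best_t, best_i, best_j = -np.inf, 0, n
    for k in range(1, n):
        seg = S[k:] - S[:n - k + 1]
        t = np.abs((seg / k - (tot - seg) / (n - k))
                   / (s * np.sqrt(1.0 / k + 1.0 / (n - k))))
        i = int(np.argmax(t))
        if t[i] > best_t:
            best_t, best_i, best_j = float(t[i]), i, i + k
    return best_t, best_i, best_j


def _perm_max_t(xp: np.ndarray) -> np.ndarray:
    """Row-wise maximal arc |t| for a batch of permuted series."""
    b, n = xp.shape
    s = np.std(xp, ddof=1, axis=1)
    s[s == 0] = np.inf
    S = np.concatenate([np.zeros((b, 1)), np.cumsum(xp, axis=1)], axis=1)
    tot = S[:, -1:]
    best = np.zeros(b)
    for k in range(1, n):
        seg = S[:, k:] - S[:, :n - k + 1]
        t = np.abs((seg / k - (tot - seg) / (n - k))
                   / (s[:, None] * np.sqrt(1.0 / k + 1.0 / (n - k))))
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _split_significant(x, t_obs, rng, alpha, n_perm) -> bool:
    """Permutation p-value with early stop once alpha is unreachable.

    ``p = (1 + #exceedances) / (1 + n_perm)``; drawing stops as soon as
    the exceedance count already forces ``p >= alpha``.
    """
    limit = alpha * (1 + n_perm)
    count = 0
    drawn = 0
    while drawn < n_perm:
        c = min(_PERM_CHUNK, n_perm - drawn)
        xp = np.stack([rng.permutation(x) for _ in range(c)])
        count += int((_perm_max_t(xp) >= t_obs).sum())
        drawn += c
        if count + 1 >= limit:
            return False
    return (1 + count) / (1 + n_perm) < alpha


def _recurse(x, start, end, seed, alpha, n_perm, cuts):
    n = end - start
    if n < 4:
        return
    t_obs, i, j = _max_arc_t(x[start:end])
    if t_obs == 0.0:
        return
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(start), int(end)]))
    if not _split_significant(x[start:end], t_obs, rng, alpha, n_perm):
        return
    for b in (start + i, start + j):
        if start < b < end:
            cuts.add(b)
    for lo, hi in ((start, start + i), (start + i, start + j),
                   (start + j, end)):
        if hi - lo > 0 and (lo, hi) != (start, end):
            _recurse(x, lo, hi, seed, alpha, n_perm, cuts)


def _merge_short(boundaries, x, min_probes):
    """Dissolve segments below min_probes into their neighbors.

    Both boundaries of a too-short segment are removed, fusing it with
    the flanking segments, so a sub-minimum event disappears rather
    than leaving a residual breakpoint.
    """
    bounds = list(boundaries)
    while len(bounds) > 2:
        lengths = np.diff(bounds)
        k = int(np.argmin(lengths))
        if lengths[k] >= min_probes:
            break
        if k == 0:
            del bounds[1]
        elif k == len(lengths) - 1:
            del bounds[-2]
        else:
            del bounds[k:k + 2]
    return bounds


def cbs_segment(positions, values, alpha: float = DEFAULT_ALPHA,
                n_permutations: int = DEFAULT_N_PERMUTATIONS,
                min_probes: int = DEFAULT_MIN_PROBES,
                seed: int = 0) -> pd.DataFrame:
    """Segment one ordered series with circular binary segmentation.

    Returns one row per segment with 1-based inclusive bp bounds, the
    probe count and the segment mean.  Deterministic for a fixed seed:
    the permutation generator for the sub-series ``[start, end)`` is
    seeded from ``(seed, start, end)`` so results do not depend on
    recursion order.  A series shorter than ``min_probes`` comes back
    as a single segment.
    """
    positions = np.asarray(positions)
    x = np.asarray(values, dtype=float)
    if len(x) != len(positions):
        raise ValueError("positions and values must align")
    if np.any(np.diff(positions) < 0):
        raise ValueError("series must be ordered by position")
    if min_probes < 2:
        raise ValueError("min_probes must be >= 2")
    n = len(x)
    if n == 0:
        return pd.DataFrame(columns=["start_idx", "end_idx", "start_bp",
                                     "end_bp", "n_probes", "mean"])
    cuts: set[int] = set()
    if n >= min_probes:
        _recurse(x, 0, n, seed, alpha, n_permutations, cuts)
    bounds = _merge_short([0] + sorted(cuts) + [n], x, min_probes)
    rows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        rows.append((lo, hi - 1, int(positions[lo]), int(positions[hi - 1]),
                     hi - lo, float(x[lo:hi].mean())))
    return pd.DataFrame(rows, columns=["start_idx", "end_idx", "start_bp",
                                       "end_bp", "n_probes", "mean"])


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class CNVThresholds:
    """Classification thresholds (canonical Infinium expectations)."""
    gain_lrr: float = 0.10
    loss_lrr: float = -0.15
    neutral_lrr: float = 0.05   # |LRR| below this is copy-neutral
    neutral_band: float = 0.10  # |LRR| below this with quiet mBAF is no event
    mbaf_elevated: float = 0.55
    mbaf_loss: float = 0.90
    mbaf_loh: float = 0.95


def _classify_interval(mean_lrr, mean_mbaf, th: CNVThresholds) -> str:
    no_baf = mean_mbaf is None or np.isnan(mean_mbaf)
    if mean_lrr >= th.gain_lrr and (no_baf or mean_mbaf >= th.mbaf_elevated):
        return "gain"
    if mean_lrr <= th.loss_lrr and (no_baf or mean_mbaf >= th.mbaf_loss):
        return "loss"
    if abs(mean_lrr) < th.neutral_lrr and not no_baf:
        if mean_mbaf >= th.mbaf_loh:
            return "cnloh"
        if th.mbaf_elevated <= mean_mbaf < th.mbaf_loh:
            return "mosaic_cnloh"
    if abs(mean_lrr) < th.neutral_band and (no_baf
                                            or mean_mbaf < th.mbaf_elevated):
        return "neutral"
    return "undetermined"


def classify_segments(lrr_series: pd.DataFrame, mbaf_series: pd.DataFrame,
                      lrr_segments: pd.DataFrame, mbaf_segments: pd.DataFrame,
                      thresholds: CNVThresholds | None = None,
                      min_probes: int = DEFAULT_MIN_PROBES) -> pd.DataFrame:
    """Classify one sample-chromosome from both segmentations.

    Interval boundaries are the union of breakpoints from the LRR and
    mBAF segmentations; each atomic interval's mean LRR and mean mBAF
    are recomputed directly from the raw series inside it (robust when
    one track saw no breakpoint), adjacent intervals of equal class are
    merged, neutral intervals dropped, and events spanning fewer than
    ``min_probes`` LRR probes discarded.  ``undetermined`` rows carry
    ``flagged=True`` for manual review.

    ``lrr_series`` needs columns position/lrr, ``mbaf_series``
    position/mbaf.
    """
    th = thresholds or CNVThresholds()
    lpos = lrr_series["position"].to_numpy()
    lval = lrr_series["lrr"].to_numpy(dtype=float)
    mpos = mbaf_series["position"].to_numpy()
    mval = mbaf_series["mbaf"].to_numpy(dtype=float)
    if len(lpos) == 0:
        return _empty_events()

    cutpoints = set()
    for seg in (lrr_segments, mbaf_segments):
        if seg is not None and len(seg) > 1:
            cutpoints.update(int(b) for b in seg["start_bp"].iloc[1:])
    lo_all = int(lpos.min())
    hi_all = int(lpos.max())
    edges = [lo_all] + sorted(c for c in cutpoints if lo_all < c <= hi_all) \
        + [hi_all + 1]

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lm = (lpos >= lo) & (lpos < hi)
        if not lm.any():
            continue
        mm = (mpos >= lo) & (mpos < hi)
        mean_lrr = float(lval[lm].mean())
        mean_mbaf = float(mval[mm].mean()) if mm.any() else np.nan
        cls = _classify_interval(mean_lrr, mean_mbaf, th)
        rows.append([int(lpos[lm].min()), int(lpos[lm].max()),
                     int(lm.sum()), mean_lrr, mean_mbaf, cls])

    # merge adjacent intervals of the same class
    merged = []
    for r in rows:
        if merged and merged[-1][5] == r[5]:
            prev = merged[-1]
            n1, n2 = prev[2], r[2]
            prev[1] = r[1]
            prev[2] = n1 + n2
            prev[3] = (prev[3] * n1 + r[3] * n2) / (n1 + n2)
            if not np.isnan(r[4]):
                prev[4] = r[4] if np.isnan(prev[4]) else (prev[4] + r[4]) / 2
        else:
            merged.append(list(r))

    out = []
    for start_bp, end_bp, n_probes, mean_lrr, mean_mbaf, cls in merged:
        if cls == "neutral" or n_probes < min_probes:
            continue
        frac = (float(np.clip(2 * (mean_mbaf - 0.5), 0, 1))
                if cls == "mosaic_cnloh" else np.nan)
        out.append((start_bp, end_bp, n_probes, mean_lrr, mean_mbaf, cls,
                    frac, cls == "undetermined"))
    return pd.DataFrame(out, columns=["start_bp", "end_bp", "n_probes",
                                      "mean_lrr", "mean_mbaf", "class",
                                      "mosaic_fraction", "flagged"])


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["start_bp", "end_bp", "n_probes", "mean_lrr",
                                 "mean_mbaf", "class", "mosaic_fraction",
                                 "flagged"])


def call_cnvs(calls: pd.DataFrame, manifest: pd.DataFrame, sample_id: str,
              alpha: float = DEFAULT_ALPHA,
              n_permutations: int = DEFAULT_N_PERMUTATIONS,
              min_probes: int = DEFAULT_MIN_PROBES,
              delta: float = DEFAULT_DELTA,
              thresholds: CNVThresholds | None = None,
              seed: int = 0) -> pd.DataFrame:
    """Segment and classify every chromosome of one sample."""
    sub = calls[calls["sample_id"] == sample_id]
    sub = sub.merge(manifest[["probe_id", "chromosome", "position"]],
                    on="probe_id")
    mb = mirrored_baf(sub, manifest, delta=delta)
    events = []
    for ci, (chrom, grp) in enumerate(sub.groupby("chromosome", sort=True)):
        grp = grp.sort_values("position")
        lrr_series = grp[["position", "lrr"]].dropna()
        mbaf_series = mb[mb["chromosome"] == chrom][["position", "mbaf"]]
        lseg = cbs_segment(lrr_series["position"], lrr_series["lrr"],
                           alpha, n_permutations, min_probes,
                           seed=seed * 1000 + 2 * ci)
        mseg = cbs_segment(mbaf_series["position"], mbaf_series["mbaf"],
                           alpha, n_permutations, min_probes,
                           seed=seed * 1000 + 2 * ci + 1)
        ev = classify_segments(lrr_series, mbaf_series, lseg, mseg,
                               thresholds, min_probes)
        if len(ev):
            ev.insert(0, "chromosome", chrom)
            events.append(ev)
    if not events:
        out = _empty_events()
        out.insert(0, "chromosome", pd.Series(dtype=object))
    else:
        out = pd.concat(events, ignore_index=True)
    out.insert(0, "sample_id", sample_id)
    return out


# ---------------------------------------------------------------------------
# Matched-pair concordance and noise gate
# ---------------------------------------------------------------------------

@dataclass
class CNVConcordance:
    n_events_reference: int
    n_tp: int
    n_fn: int
    n_fp: int

    @property
    def concordance_rate(self) -> float:
        return (self.n_tp / self.n_events_reference
                if self.n_events_reference else float("nan"))


def _reciprocal_overlap(s1, e1, s2, e2) -> float:
    ov = min(e1, e2) - max(s1, s2) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1 + 1), ov / (e2 - s2 + 1))


def match_events(reference: pd.DataFrame, test: pd.DataFrame,
                 min_reciprocal_overlap: float = DEFAULT_OVERLAP) -> CNVConcordance:
    """TP/FN/FP accounting between matched samples of one individual.

    One-to-one matching is an optimal assignment (maximum cardinality,
    then maximum total overlap) over pairs with the same chromosome and
    class and reciprocal overlap above the threshold, so the accounting
    is anti-symmetric: swapping reference and test swaps FN and FP.
    """
    from scipy.optimize import linear_sum_assignment

    t_rows = test.to_dict("records")
    r_rows = reference.to_dict("records")
    tp = 0
    if r_rows and t_rows:
        weight = np.zeros((len(r_rows), len(t_rows)))
        for i, ref in enumerate(r_rows):
            for k, t in enumerate(t_rows):
                if (t["chromosome"] != ref["chromosome"]
                        or t["class"] != ref["class"]):
                    continue
                ov = _reciprocal_overlap(ref["start_bp"], ref["end_bp"],
                                         t["start_bp"], t["end_bp"])
                if ov >= min_reciprocal_overlap:
                    # +1 ranks match count above summed overlap
                    weight[i, k] = 1.0 + ov
        rows, cols = linear_sum_assignment(weight, maximize=True)
        tp = int((weight[rows, cols] > 0).sum())
    return CNVConcordance(
        n_events_reference=len(reference),
        n_tp=tp,
        n_fn=len(reference) - tp,
        n_fp=len(test) - tp,
    )


def noise_gate(lrr_sd: pd.Series, sd_threshold: float = DEFAULT_SD_GATE) -> pd.Series:
    """Eligibility for CNV calling: post-normalization LRR sd gate."""
    return lrr_sd <= sd_threshold
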