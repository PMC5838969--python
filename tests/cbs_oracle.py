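"""Independent exhaustive change-point oracle for CBS cross-checking.

Re-implements recursive maximal-|t| segmentation with explicit loops —
no code shared with the package implementation.  The *statistical
protocol* (t definition, permutation schedule seeded per sub-series,
chunked draws with early stop, acceptance rule, short-segment
dissolution) is part of the method's definition and therefore fixed
identically here; the arc search, statistic evaluation and recursion
bookkeeping are written independently so they can disagree if either
side is wrong.
"""

import numpy as np

_CHUNK = 64


def _max_t_bruteforce(x):
    """Max |t| over every arc via explicit (length, start) loops."""
    n = len(x)
    s = float(np.std(x, ddof=1))
    if s == 0:
        return 0.0, 0, n
    csum = np.cumsum(x)
    total = float(csum[-1])
    best_t, best_i, best_j = -np.inf, 0, n
    for k in range(1, n):
        denom = s * np.sqrt(1.0 / k + 1.0 / (n - k))
        for i in range(n - k + 1):
            seg = float(csum[i + k - 1]) - (float(csum[i - 1]) if i else 0.0)
            t = abs((seg / k - (total - seg) / (n - k)) / denom)
            if t > best_t:
                best_t, best_i, best_j = t, i, i + k
    return best_t, best_i, best_j


def _significant(x, t_obs, rng, alpha, n_perm):
    limit = alpha * (1 + n_perm)
    count = 0
    drawn = 0
    while drawn < n_perm:
        c = min(_CHUNK, n_perm - drawn)
        perms = [rng.permutation(x) for _ in range(c)]
        for p in perms:
            t, _, _ = _max_t_bruteforce(p)
            if t >= t_obs:
                count += 1
        drawn += c
        if count + 1 >= limit:
            return False
    return (1 + count) / (1 + n_perm) < alpha


def _recurse(x, start, end, seed, alpha, n_perm, cuts):
    if end - start < 4:
        return
    t_obs, i, j = _max_t_bruteforce(x[start:end])
    if t_obs == 0.0:
        return
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(start), int(end)]))
    if not _significant(x[start:end], t_obs, rng, alpha, n_perm):
        return
    if 0 < i:
        cuts.add(start + i)
    if j < end - start:
        cuts.add(start + j)
    children = [(start, start + i), (start + i, start + j), (start + j, end)]
    for lo, hi in children:
        if hi > lo and (lo, hi) != (start, end):
            _recurse(x, lo, hi, seed, alpha, n_perm, cuts)


def oracle_breakpoints(values, alpha, n_permutations, min_probes, seed):
    """Boundary index list [0, ..., n] after recursion and dissolution."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    cuts: set[int] = set()
    if n >= min_probes:
        _recurse(x, 0, n, seed, alpha, n_permutations, cuts)
    bounds = [0] + sorted(cuts) + [n]
    while len(bounds) > 2:
        lengths = [b - a for a, b in zip(bounds[:-1], bounds[1:])]
        k = min(range(len(lengths)), key=lambda idx: lengths[idx])
        if lengths[k] >= min_probes:
            break
        if k == 0:
            bounds.pop(1)
        elif k == len(lengths) - 1:
            bounds.pop(-2)
        else:
            bounds.pop(k + 1)
            bounds.pop(k)
    return bounds
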