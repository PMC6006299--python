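"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: posterior probabilities
by exhaustive path enumeration, changepoints by exhaustive split search,
distances by all-pairs scans.
"""

from __future__ import annotations

import numpy as np

from xomap.cocall import emission_loglik, switch_probability


def enumerate_posterior(alt, ref, pos, cfg) -> np.ndarray:
    """P(HET) per marker by summing over all 2^m state paths (vectorised)."""
    alt = np.asarray(alt, dtype=np.int64)
    ref = np.asarray(ref, dtype=np.int64)
    pos = np.asarray(pos, dtype=float)
    m = alt.size
    depth = alt + ref
    le_hom, le_het = emission_loglik(alt, depth, cfg.error_eps)
    sw = switch_probability(np.diff(pos), cfg.switch_tau)
    paths = ((np.arange(2**m)[:, None] >> np.arange(m)[None, :]) & 1).astype(bool)
    ll = np.where(paths, le_het, le_hom).sum(axis=1) + np.log(0.5)
    if m > 1:
        flips = paths[:, 1:] != paths[:, :-1]
        ll += np.where(flips, np.log(sw), np.log1p(-sw)).sum(axis=1)
    w = np.exp(ll - ll.max())
    return (w[:, None] * paths).sum(axis=0) / w.sum()


def best_single_split(y: np.ndarray) -> int:
    """Exhaustive best single changepoint (min total SSE) on a series."""
    def sse(v):
        return float(((v - v.mean()) ** 2).sum()) if v.size else 0.0

    costs = [sse(y[:s]) + sse(y[s:]) for s in range(1, y.size)]
    return int(np.argmin(costs)) + 1


def best_double_split(y: np.ndarray) -> tuple[int, int]:
    """Exhaustive best pair of changepoints on a short series."""
    def sse(v):
        return float(((v - v.mean()) ** 2).sum()) if v.size else 0.0

    best, arg = np.inf, (1, 2)
    for s1 in range(1, y.size - 1):
        left = sse(y[:s1])
        for s2 in range(s1 + 1, y.size):
            c = left + sse(y[s1:s2]) + sse(y[s2:])
            if c < best:
                best, arg = c, (s1, s2)
    return arg


def brute_nearest_distance(pos: float, starts, ends) -> float:
    """Unsigned distance to the nearest feature by scanning every feature."""
    best = np.inf
    for s, e in zip(starts, ends):
        if s <= pos < e:
            return 0.0
        best = min(best, abs(pos - s), abs(pos - (e - 1)))
    return best


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| over the pooled sample points."""
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), pooled, side="right") / a.size
    fb = np.searchsorted(np.sort(b), pooled, side="right") / b.size
    return float(np.abs(fa - fb).max())
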