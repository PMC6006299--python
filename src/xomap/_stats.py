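"""Vectorised small-sample statistics used across the pipeline."""

from __future__ import annotations

import numpy as np
from scipy import stats


def fisher_exact_two_sided(
    n11: np.ndarray, n10: np.ndarray, n01: np.ndarray, n00: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p for many 2x2 tables at once.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more likely than the observed one. Uses a log-factorial
    lookup table, so the cost is O(max_n) vectorised passes over the input
    arrays rather than one scipy call per table. Agrees with
    scipy.stats.fisher_exact to numerical precision (tested).
    """
    n11 = np.asarray(n11, dtype=np.int64)
    n10 = np.asarray(n10, dtype=np.int64)
    n01 = np.asarray(n01, dtype=np.int64)
    n00 = np.asarray(n00, dtype=np.int64)
    r1 = n11 + n10
    c1 = n11 + n01
    n = n11 + n10 + n01 + n00
    if n.size == 0:
        return np.empty(0)
    lf = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, int(n.max()) + 2)))])

    def logpmf(k):
        return (
            lf[r1] + lf[n - r1] + lf[c1] + lf[n - c1]
            - lf[n] - lf[k] - lf[r1 - k] - lf[c1 - k] - lf[n - r1 - c1 + k]
        )

    lo = np.maximum(0, r1 + c1 - n)
    hi = np.minimum(r1, c1)
    lp_obs = logpmf(n11)
    p = np.zeros(n.shape, dtype=float)
    # relative tolerance matching scipy's treatment of ties in pmf
    tol = lp_obs + 1e-7
    for k in range(int(hi.max()) + 1):
        kk = np.full(n.shape, k, dtype=np.int64)
        valid = (kk >= lo) & (kk <= hi)
        kk = np.where(valid, kk, lo)  # safe index; masked out below
        lp = logpmf(kk)
        p += np.where(valid & (lp <= tol), np.exp(lp), 0.0)
    return np.minimum(p, 1.0)


def g_test_2x2(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Likelihood-ratio (G) test of equal binomial proportions.

    G = 2 * sum O * ln(O/E) over the 2x2 table [[k1, n1-k1], [k2, n2-k2]]
    with expectations from the margins; p from chi2 with 1 df. Zero cells
    contribute 0 (lim x->0 of x ln x).
    """
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n for both samples")
    if n1 == 0 or n2 == 0:
        raise ValueError("sample sizes must be positive")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum()
    g = max(g, 0.0)
    return float(g), float(stats.chi2.sf(g, df=1))


def z_test_two_sided(values: np.ndarray, null: float = 0.0) -> tuple[float, float]:
    """Z statistic and two-sided p of a sample mean against a null value.

    Used on bootstrap-replicate distributions (replicate SD, not SE of the
    mean, following the resampling convention of representativeness tests).
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        return (np.inf if values.mean() != null else 0.0), (0.0 if values.mean() != null else 1.0)
    z = (values.mean() - null) / sd
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
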