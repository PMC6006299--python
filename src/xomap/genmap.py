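"""Genetic maps per sex: interval recombination fractions, Haldane distances,
Marey tables and male-female interval tests with multiple-testing control.

The physical marker order is taken as known (reference genome), so distances
reduce to two-point recombination fractions in fixed 1-Mbp intervals: an
individual is recombinant for an interval when a CO midpoint falls inside
it, r = n_recombinant / n_total, and the Haldane mapping function converts
r to centimorgans.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import g_test_2x2


def haldane_cm(r) -> np.ndarray | float:
    """Haldane map distance d = -50 ln(1 - 2r) in cM; requires 0 <= r < 0.5."""
    arr = np.asarray(r, dtype=float)
    if np.any((arr < 0) | (arr >= 0.5)):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = -50.0 * np.log1p(-2.0 * arr)
    return float(d) if np.isscalar(r) else d


def make_intervals(chrom_lengths: dict[str, int], interval_bp: int = 1_000_000) -> pd.DataFrame:
    """Tile each chromosome with half-open intervals of interval_bp.

    Boundary sites are synthetic where no marker exists, so every interval
    is exactly interval_bp except a shorter terminal one.
    """
    rows = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L, interval_bp)
        ends = np.minimum(starts + interval_bp, L)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def interval_recombination(
    events: pd.DataFrame,
    n_total: int,
    chrom_lengths: dict[str, int],
    interval_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Per-interval recombination fraction and Haldane distance for one sex.

    An individual counts once per interval however many of its CO midpoints
    fall inside (midpoint rule, half-open bins). Total chromosome cM is the
    sum over its intervals by construction.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    intervals = make_intervals(chrom_lengths, interval_bp)
    k = np.zeros(len(intervals), dtype=int)
    index = {
        (row.chrom, int(row.start)): i for i, row in enumerate(intervals.itertuples())
    }
    if len(events):
        mids = events["midpoint"].to_numpy()
        bins = (mids // interval_bp).astype(int) * interval_bp
        seen = set()
        for ind, chrom, b in zip(events["individual"], events["chrom"], bins):
            key = (ind, chrom, int(b))
            if key in seen:
                continue
            seen.add(key)
            k[index[(chrom, int(b))]] += 1
    out = intervals.copy()
    out["n_recombinant"] = k
    out["n_total"] = n_total
    out["r"] = k / n_total
    out["cm"] = haldane_cm(out["r"].to_numpy())
    return out


def sex_interval_tests(
    male_map: pd.DataFrame, female_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-interval G tests of equal recombination fractions, with
    Bonferroni, Benjamini-Hochberg and Benjamini-Yekutieli adjusted p."""
    if len(male_map) != len(female_map):
        raise ValueError("interval grids differ between sexes")
    g = np.empty(len(male_map))
    p = np.empty(len(male_map))
    for i, (km, nm, kf, nf) in enumerate(
        zip(
            male_map["n_recombinant"], male_map["n_total"],
            female_map["n_recombinant"], female_map["n_total"],
        )
    ):
        g[i], p[i] = g_test_2x2(int(km), int(nm), int(kf), int(nf))
    out = male_map[["chrom", "start", "end"]].copy()
    out["g"] = g
    out["p"] = p
    out["p_bonferroni"] = multipletests(p, method="bonferroni")[1]
    out["p_bh"] = multipletests(p, method="fdr_bh")[1]
    out["p_by"] = multipletests(p, method="fdr_by")[1]
    return out


def marey_table(map_df: pd.DataFrame) -> pd.DataFrame:
    """Cumulative genetic distance against physical position per chromosome.

    One row per interval end: (chrom, pos_bp, cum_cm). Monotone
    non-decreasing; the curve endpoint equals the chromosome's total cM.
    """
    rows = []
    for chrom, sub in map_df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cum = np.concatenate([[0.0], np.cumsum(sub["cm"].to_numpy())])
        pos = np.concatenate([[sub["start"].iloc[0]], sub["end"].to_numpy()])
        rows.append(pd.DataFrame({"chrom": chrom, "pos_bp": pos, "cum_cm": cum}))
    return pd.concat(rows, ignore_index=True)


def chromosome_totals(map_df: pd.DataFrame) -> pd.DataFrame:
    """Total cM and physical length per chromosome (for length~cM regression)."""
    out = (
        map_df.groupby("chrom", sort=False)
        .agg(length_bp=("end", "max"), total_cm=("cm", "sum"))
        .reset_index()
    )
    return out
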