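"""Genomic and chromatin context of crossover sites.

Distances from CO midpoints to genes/TEs, enrichment against random
placement, strand-oriented metaplots of CO density or chromatin signal
around anchors (TSS, TTS, CO sites), bootstrap tests of metaplot peak
positions, and scaled-region profiles for features of unequal length
(knobs, chromosome ends).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationSet, SignalTrack


# ---------------------------------------------------------------------------
# distances to features


def distance_to_nearest(
    points: pd.DataFrame, features: pd.DataFrame, signed: bool = False
) -> pd.DataFrame:
    """Distance from each point (CO midpoint) to its nearest feature.

    Unsigned distance is 0 inside a feature, else bp to the nearest feature
    edge. With ``signed=True`` (gene features with a strand column) the
    sign is strand-oriented: upstream of the feature is negative,
    downstream positive. Points on chromosomes absent from the annotation
    get NaN (skipped, counted in the log).

    ``points`` needs columns (chrom, pos); ``features`` (chrom, start, end
    [, strand]).
    """
    points = points.reset_index(drop=True)
    out_dist = np.full(len(points), np.nan)
    out_signed = np.full(len(points), np.nan)
    for chrom, sub in points.groupby("chrom"):
        feats = features[features["chrom"] == chrom]
        if len(feats) == 0:
            continue
        starts = feats["start"].to_numpy()
        ends = feats["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        strands = (
            feats["strand"].to_numpy()[order]
            if signed and "strand" in feats.columns
            else None
        )
        cummax_end = np.maximum.accumulate(ends)
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right")
        inside = (idx > 0) & (pos < cummax_end[np.maximum(idx - 1, 0)])
        # distance to nearest edge among the left neighbour's end and the
        # right neighbour's start (overlaps resolved by the cummax check)
        left_end = np.where(idx > 0, cummax_end[np.maximum(idx - 1, 0)], -np.inf)
        right_start = np.where(
            idx < len(starts), starts[np.minimum(idx, len(starts) - 1)], np.inf
        )
        d_left = pos - (left_end - 1)  # bp beyond the last covered base
        d_right = right_start - pos
        dist = np.where(inside, 0.0, np.minimum(d_left, d_right))
        sgn = np.zeros(len(pos))
        if strands is not None:
            # sign relative to the nearest feature's orientation
            use_left = d_left <= d_right
            near_idx = np.where(use_left, np.maximum(idx - 1, 0), np.minimum(idx, len(starts) - 1))
            near_strand = strands[near_idx]
            # left of a + gene (or right of a - gene) is upstream => negative
            before = ~use_left  # point lies before the nearest feature start
            upstream = np.where(near_strand == "+", before, ~before)
            sgn = np.where(inside, 0.0, np.where(upstream, -dist, dist))
        out_dist[sub.index.to_numpy()] = dist
        out_signed[sub.index.to_numpy()] = sgn if strands is not None else np.nan
    res = points.copy()
    res["distance"] = out_dist
    if signed:
        res["signed_distance"] = out_signed
    return res


def fraction_within(distances: np.ndarray, threshold: float = 10_000.0) -> float:
    """Fraction of points within a distance threshold of a feature."""
    d = np.asarray(distances, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no finite distances")
    return float((d <= threshold).mean())


def genes_near_events(
    events: pd.DataFrame, genes: pd.DataFrame, threshold: float = 10_000.0
) -> list[str]:
    """Unique gene ids within ``threshold`` bp of any CO midpoint."""
    hits: set[str] = set()
    for chrom, sub in events.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g["gene_id"].to_numpy()
        for mid in sub["midpoint"].to_numpy():
            near = (mid >= starts - threshold) & (mid < ends + threshold)
            hits.update(ids[near])
    return sorted(hits)


def random_placement_test(
    observed: pd.DataFrame,
    features: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_random: int,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon test of observed vs random feature distances.

    Places n_random uniform midpoints over the mappable genome (here the
    whole assembly) and compares the two unsigned distance distributions
    two-sided. Returns (U statistic, p).
    """
    if n_random <= 0:
        raise ValueError("n_random must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n_random, p=lens / lens.sum())
    rand = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in pick],
            "pos": (rng.random(n_random) * lens[pick]).astype(int),
        }
    )
    d_obs = distance_to_nearest(observed, features)["distance"].dropna().to_numpy()
    d_rand = distance_to_nearest(rand, features)["distance"].dropna().to_numpy()
    u, p = stats.mannwhitneyu(d_obs, d_rand, alternative="two-sided")
    return float(u), float(p)


# ---------------------------------------------------------------------------
# anchored metaplots


@dataclass
class ProfileResult:
    """Binned metaplot around anchors (or across scaled regions).

    ``centers``: bin centres in relative bp (or fractional units for scaled
    profiles); ``values``: mean signal or CO count per bin; ``n``: anchors
    (signal mode) or contributing positions (density mode); ``peak``: centre
    of the (smoothed) argmax bin, ties broken leftmost;
    ``contributions``: per-anchor rows (signal mode) or the flat relative
    positions (density mode) retained for bootstrap resampling.
    """

    centers: np.ndarray
    values: np.ndarray
    n: int
    peak: float
    contributions: np.ndarray
    mode: str
    n_truncated: int = 0
    smooth: int = 3

    def recompute_peak(self) -> float:
        self.peak = _profile_peak(self.centers, self.values, self.smooth)
        return self.peak


def _smooth_values(values: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return values
    v = np.nan_to_num(values, nan=0.0)
    kernel = np.ones(k) / k
    return np.convolve(v, kernel, mode="same")


def _profile_peak(centers: np.ndarray, values: np.ndarray, smooth: int) -> float:
    sm = _smooth_values(values, smooth)
    return float(centers[int(np.argmax(sm))])  # argmax is leftmost on ties


def _relative_bins(flank: int, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(-flank, flank + bin_size, bin_size, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return edges, centers


def anchored_density_profile(
    points: pd.DataFrame,
    anchors: pd.DataFrame,
    flank: int = 2_000,
    bin_size: int = 50,
    smooth: int = 3,
) -> ProfileResult:
    """Histogram of point positions relative to strand-oriented anchors.

    Each (anchor, point) pair with |point - anchor| < flank contributes
    once; minus-strand anchors flip the relative coordinate. The profile
    integrates to the number of contributing pairs.
    """
    edges, centers = _relative_bins(flank, bin_size)
    rel_all: list[np.ndarray] = []
    for chrom, asub in anchors.groupby("chrom"):
        psub = points[points["chrom"] == chrom]
        if len(psub) == 0:
            continue
        ppos = np.sort(psub["pos"].to_numpy(dtype=float))
        apos = asub["pos"].to_numpy(dtype=float)
        orient = (
            np.where(asub["strand"].to_numpy() == "-", -1.0, 1.0)
            if "strand" in asub.columns
            else np.ones(len(asub))
        )
        for a, o in zip(apos, orient):
            lo = np.searchsorted(ppos, a - flank)
            hi = np.searchsorted(ppos, a + flank)
            if hi > lo:
                rel_all.append((ppos[lo:hi] - a) * o)
    rel = np.concatenate(rel_all) if rel_all else np.empty(0)
    counts, _ = np.histogram(rel, bins=edges)
    values = counts.astype(float)
    return ProfileResult(
        centers=centers,
        values=values,
        n=int(rel.size),
        peak=_profile_peak(centers, values, smooth),
        contributions=rel,
        mode="density",
        smooth=smooth,
    )


def anchored_signal_profile(
    track: SignalTrack,
    anchors: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank: int = 2_000,
    bin_size: int = 50,
    smooth: int = 3,
) -> ProfileResult:
    """Mean track signal per relative bin over strand-oriented anchors.

    Bins falling beyond a chromosome edge contribute NaN for that anchor
    (truncated contribution, counted in ``n_truncated``).
    """
    edges, centers = _relative_bins(flank, bin_size)
    nb = len(centers)
    rows = []
    n_trunc = 0
    for _, row in anchors.iterrows():
        chrom = row["chrom"]
        if chrom not in track.values:
            continue
        a = float(row["pos"])
        o = -1.0 if ("strand" in anchors.columns and row["strand"] == "-") else 1.0
        L = chrom_lengths[chrom]
        vals = np.empty(nb)
        truncated = False
        for i in range(nb):
            lo, hi = a + o * edges[i], a + o * edges[i + 1]
            lo, hi = (lo, hi) if lo <= hi else (hi, lo)
            if lo < 0 or hi > L:
                vals[i] = np.nan
                truncated = True
            else:
                vals[i] = track.mean(chrom, lo, hi)
        if truncated:
            n_trunc += 1
        rows.append(vals)
    if not rows:
        raise ValueError("no usable anchors")
    mat = np.vstack(rows)
    values = np.nanmean(mat, axis=0)
    return ProfileResult(
        centers=centers,
        values=values,
        n=mat.shape[0],
        peak=_profile_peak(centers, values, smooth),
        contributions=mat,
        mode="signal",
        n_truncated=n_trunc,
        smooth=smooth,
    )


# ---------------------------------------------------------------------------
# profile comparison tests


@dataclass
class PeakTestResult:
    delta_peak: float
    p_z: float
    replicates_a: np.ndarray
    replicates_b: np.ndarray


def _bootstrap_peaks(
    profile: ProfileResult, b: int, rng: np.random.Generator
) -> np.ndarray:
    step = profile.centers[1] - profile.centers[0] if len(profile.centers) > 1 else 1.0
    edges = np.concatenate([profile.centers - step / 2.0, [profile.centers[-1] + step / 2.0]])
    peaks = np.empty(b)
    contrib = profile.contributions
    n = contrib.shape[0]
    for i in range(b):
        idx = rng.integers(0, n, size=n)
        if profile.mode == "density":
            counts, _ = np.histogram(contrib[idx], bins=edges)
            vals = counts.astype(float)
        else:
            vals = np.nanmean(contrib[idx], axis=0)
        peaks[i] = _profile_peak(profile.centers, vals, profile.smooth)
    return peaks


def profile_peak_test(
    a: ProfileResult,
    b: ProfileResult,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PeakTestResult:
    """Bootstrap Z test of the peak-position difference between two profiles.

    CO positions (density mode) or anchors (signal mode) are resampled with
    replacement n_boot times per group; the peak of each replicate profile
    is located (smoothed argmax, leftmost on ties) and the replicate
    peak-difference distribution is tested against 0, two-sided.
    """
    if len(a.centers) != len(b.centers) or not np.allclose(a.centers, b.centers):
        raise ValueError("profiles must share a binning")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pa = _bootstrap_peaks(a, n_boot, rng)
    pb = _bootstrap_peaks(b, n_boot, rng)
    diffs = pa - pb
    sd = diffs.std(ddof=1)
    if sd == 0:
        p = 1.0 if diffs.mean() == 0 else 0.0
    else:
        z = diffs.mean() / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    return PeakTestResult(
        delta_peak=a.peak - b.peak, p_z=p, replicates_a=pa, replicates_b=pb
    )


def distribution_ks_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test of relative positions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("need at least 10 positions per sample")
    d, p = stats.ks_2samp(a, b, alternative="two-sided")
    return float(d), float(p)


# ---------------------------------------------------------------------------
# scaled-region profiles


def scaled_region_profile(
    regions: pd.DataFrame,
    track: SignalTrack | None = None,
    points: pd.DataFrame | None = None,
    nbins: int = 100,
) -> ProfileResult:
    """Profile across regions equalised to unit length and split into nbins.

    Track mode averages the signal over each fractional bin (exact
    piecewise integration) and weights regions equally. Points mode
    histograms the fractional positions of points falling inside each
    region. Regions shorter than nbins bp still integrate exactly but are
    flagged via ``n_truncated``.
    """
    if len(regions) == 0:
        raise ValueError("regions must be nonempty")
    if (track is None) == (points is None):
        raise ValueError("provide exactly one of track or points")
    centers = (np.arange(nbins) + 0.5) / nbins
    short = 0
    if track is not None:
        rows = []
        for _, r in regions.iterrows():
            chrom, start, end = r["chrom"], float(r["start"]), float(r["end"])
            L = end - start
            if L < nbins:
                short += 1
            edges = start + L * np.arange(nbins + 1) / nbins
            rows.append(
                [track.mean(chrom, edges[i], edges[i + 1]) for i in range(nbins)]
            )
        mat = np.asarray(rows)
        values = np.nanmean(mat, axis=0)
        contrib = mat
        n = mat.shape[0]
    else:
        fracs = []
        for _, r in regions.iterrows():
            sub = points[points["chrom"] == r["chrom"]]
            p = sub["pos"].to_numpy(dtype=float)
            inside = p[(p >= r["start"]) & (p < r["end"])]
            L = r["end"] - r["start"]
            if L < nbins:
                short += 1
            fracs.append((inside - r["start"]) / L)
        flat = np.concatenate(fracs) if fracs else np.empty(0)
        values, _ = np.histogram(flat, bins=np.arange(nbins + 1) / nbins)
        values = values.astype(float)
        contrib = flat
        n = int(flat.size)
    return ProfileResult(
        centers=centers,
        values=values,
        n=n,
        peak=_profile_peak(centers, values, 1),
        contributions=contrib,
        mode="signal" if track is not None else "density",
        n_truncated=short,
        smooth=1,
    )
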