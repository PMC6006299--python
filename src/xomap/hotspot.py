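"""CO hotspot detection and male-female hotspot comparison.

A hotspot is a fixed 5-kbp window whose per-gamete CO rate is at least
five-fold the genome-average rate ("at least" read inclusively). Windows
are a fixed non-overlapping tiling, not sliding, so hotspot "sites" are
discrete and shared-site counting is well defined. The bootstrap
representativeness test resamples the hotspot site set with replacement
and asks whether the empirical male-female rate correlation is typical of
the resampled distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def window_rates(
    events: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_gametes: int,
    window_size: int = 5_000,
    fold_threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-window CO counts, rates and fold over the genome average.

    CO midpoints are assigned to half-open windows (a midpoint exactly on a
    boundary belongs to the right window). rate = count / (n_gametes *
    window bp); the genome average is total COs / (n_gametes * genome bp).
    """
    if n_gametes <= 0:
        raise ValueError("n_gametes must be positive")
    genome = sum(chrom_lengths.values())
    frames = []
    total = len(events)
    avg_rate = total / (n_gametes * genome) if total else 0.0
    for chrom, L in chrom_lengths.items():
        n_win = int(np.ceil(L / window_size))
        counts = np.zeros(n_win, dtype=int)
        sub = events[events["chrom"] == chrom]
        if len(sub):
            idx = (sub["midpoint"].to_numpy() // window_size).astype(int)
            np.add.at(counts, idx, 1)
        starts = np.arange(n_win) * window_size
        widths = np.minimum(starts + window_size, L) - starts
        rate = counts / (n_gametes * widths)
        fold = rate / avg_rate if avg_rate > 0 else np.zeros(n_win)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + widths,
                    "co_count": counts,
                    "rate": rate,
                    "fold": fold,
                    "is_hotspot": (fold >= fold_threshold) & (counts > 0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _check_same_grid(male: pd.DataFrame, female: pd.DataFrame) -> None:
    if len(male) != len(female) or not (
        (male["chrom"].to_numpy() == female["chrom"].to_numpy()).all()
        and (male["start"].to_numpy() == female["start"].to_numpy()).all()
    ):
        raise ValueError("male and female window grids do not match")


def shared_hotspot_stats(male: pd.DataFrame, female: pd.DataFrame) -> dict:
    """Hotspot sharing between sexes on one window grid.

    Returns counts per sex, shared (flagged in both), union (flagged in
    either), and the shared percentage of the union to the nearest integer.
    """
    _check_same_grid(male, female)
    hm = male["is_hotspot"].to_numpy(dtype=bool)
    hf = female["is_hotspot"].to_numpy(dtype=bool)
    return shared_stats_from_counts(
        int(hm.sum()), int(hf.sum()), int((hm & hf).sum())
    )


def shared_stats_from_counts(n_male: int, n_female: int, n_shared: int) -> dict:
    """Sharing arithmetic from counts alone: union and percent shared."""
    if n_shared > min(n_male, n_female):
        raise ValueError("shared count exceeds a per-sex count")
    union = n_male + n_female - n_shared
    pct = int(round(100.0 * n_shared / union)) if union else 0
    return {
        "n_male": n_male,
        "n_female": n_female,
        "n_shared": n_shared,
        "n_union": union,
        "pct_shared_of_union": pct,
    }


def hotspot_site_rates(
    male: pd.DataFrame, female: pd.DataFrame, top_fraction: float | None = None
) -> pd.DataFrame:
    """Per-sex rates at the union-of-hotspots site set.

    ``top_fraction`` keeps only the strongest sites ranked by
    max(male fold, female fold) (e.g. 0.1 for the top 10%).
    """
    _check_same_grid(male, female)
    union = male["is_hotspot"].to_numpy() | female["is_hotspot"].to_numpy()
    sites = pd.DataFrame(
        {
            "chrom": male["chrom"][union].to_numpy(),
            "start": male["start"][union].to_numpy(),
            "rate_male": male["rate"][union].to_numpy(),
            "rate_female": female["rate"][union].to_numpy(),
            "strength": np.maximum(
                male["fold"][union].to_numpy(), female["fold"][union].to_numpy()
            ),
        }
    )
    if top_fraction is not None:
        k = max(int(round(top_fraction * len(sites))), 2)
        sites = sites.nlargest(k, "strength").reset_index(drop=True)
    return sites


def hotspot_correlation(sites: pd.DataFrame) -> float:
    """Pearson correlation of male vs female CO rates over hotspot sites."""
    if len(sites) < 3:
        raise ValueError("need at least 3 sites")
    x = sites["rate_male"].to_numpy(dtype=float)
    y = sites["rate_female"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a rate vector; correlation undefined")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class BootstrapResult:
    """Bootstrap of the male-female hotspot rate correlation.

    ``p_count`` counts replicates with correlation above the empirical one
    divided by B; ``p_z`` is the Gaussian-approximation analogue
    (P(replicate > empirical) under a normal fit of the replicates), so a
    representative empirical value gives p near 0.5 under either rule.
    """

    empirical_r: float
    replicate_rs: np.ndarray
    p_count: float
    p_z: float


def bootstrap_correlation(
    sites: pd.DataFrame, b: int = 1000, seed: int | np.random.Generator = 0
) -> BootstrapResult:
    """Resample hotspot sites with replacement B times and recompute R.

    Degenerate replicates (zero variance in either rate vector) are
    redrawn and logged; exactly B replicates are always produced.
    """
    if len(sites) < 10:
        raise ValueError("need at least 10 sites to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = sites["rate_male"].to_numpy(dtype=float)
    y = sites["rate_female"].to_numpy(dtype=float)
    emp = hotspot_correlation(sites)
    n = len(x)
    reps = np.empty(b)
    redraws = 0
    for i in range(b):
        while True:
            idx = rng.integers(0, n, size=n)
            xs, ys = x[idx], y[idx]
            if xs.std() > 0 and ys.std() > 0:
                break
            redraws += 1
        reps[i] = np.corrcoef(xs, ys)[0, 1]
    if redraws:
        logger.info("bootstrap_correlation: %d degenerate replicates redrawn", redraws)
    p_count = float((reps > emp).sum() / b)
    # normal-approximation analogue of p_count: P(replicate > empirical)
    # under a Gaussian fit of the replicate distribution; ~0.5 when the
    # empirical value is representative of the resampled populations
    sd = reps.std(ddof=1)
    if sd == 0:
        p_z = 0.5 if emp == reps.mean() else (0.0 if emp < reps.mean() else 1.0)
    else:
        z = (emp - reps.mean()) / sd
        p_z = float(stats.norm.sf(z))
    return BootstrapResult(empirical_r=emp, replicate_rs=reps, p_count=p_count, p_z=p_z)
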