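"""Crossover inference from low-coverage allele depths.

The caller follows a two-stage design. Per individual and chromosome the
alt-read frequency is pooled in non-overlapping 200-kbp bins; a penalised
least-squares changepoint fit of the bin series yields candidate genotype
breakpoints (a HOM block sits near the read-error rate, a HET block near
0.5). Each candidate is then refined with a two-state hidden Markov model
over all retained SNPs in the 10-Mbp window centred on it: binomial
emissions, distance-scaled switch probabilities, posterior decoding by
forward-backward. A crossover is reported between the last marker whose
flanking-state posterior reaches ``min_posterior`` and the first marker on
the other side doing the same, so the reported interval covers the true
exchange point with calibrated confidence and flips lacking confident
flanks (structural-polymorphism noise) are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import stats

from .config import HmmConfig
from .containers import AlleleDepthMatrix, MarkerSet, events_frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# binned allele-frequency track


@dataclass
class BinFrequencyTrack:
    """Per-individual alt-read frequency in non-overlapping genomic bins.

    ``freq[chrom]`` is an (n_individuals, n_bins) float array; NaN marks
    bins without any covered read. Bins tile [0, L) half-open.
    """

    bin_size: int
    individuals: list[str]
    freq: dict[str, np.ndarray]
    bin_depth: dict[str, np.ndarray] = field(default_factory=dict)


def bin_allele_frequency(
    m: AlleleDepthMatrix,
    chrom_lengths: dict[str, int],
    bin_size: int = 200_000,
    pass_mask: np.ndarray | None = None,
) -> BinFrequencyTrack:
    """Pool alt/(alt+ref) per individual in fixed bins over retained markers."""
    if pass_mask is None:
        pass_mask = m.markers.pass_mask
    freq: dict[str, np.ndarray] = {}
    depth_out: dict[str, np.ndarray] = {}
    for chrom, L in chrom_lengths.items():
        sl = m.markers.chrom_slice(chrom)
        n_bins = int(np.ceil(L / bin_size))
        pos = m.markers.table["pos"].to_numpy()[sl]
        keep = pass_mask[sl]
        alt = m.alt[:, sl][:, keep]
        ref = m.ref[:, sl][:, keep]
        pos = pos[keep]
        edges = np.arange(1, n_bins + 1) * bin_size
        starts = np.searchsorted(pos, np.concatenate([[0], edges[:-1]]))
        # reduceat needs strictly valid starts; empty bins handled after
        alt_sum = np.zeros((m.n_individuals, n_bins))
        tot_sum = np.zeros((m.n_individuals, n_bins))
        if pos.size:
            safe = np.minimum(starts, pos.size - 1)
            a = np.add.reduceat(alt, safe, axis=1)
            t = np.add.reduceat(alt + ref, safe, axis=1)
            empty = starts >= np.append(starts[1:], pos.size)
            a[:, empty] = 0
            t[:, empty] = 0
            alt_sum, tot_sum = a.astype(float), t.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[chrom] = np.where(tot_sum > 0, alt_sum / np.maximum(tot_sum, 1), np.nan)
        depth_out[chrom] = tot_sum
    return BinFrequencyTrack(
        bin_size=bin_size, individuals=list(m.individuals), freq=freq, bin_depth=depth_out
    )


# ---------------------------------------------------------------------------
# changepoint segmentation of one bin series


def _optimal_partition(y: np.ndarray, beta: float) -> list[int]:
    """Exact DP minimising total within-segment SSE + beta per extra segment.

    Returns the split indices (a split at s means segments y[:s], y[s:]).
    """
    n = y.size
    s = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    idx = np.arange(n + 1)
    for j in range(1, n + 1):
        i = idx[:j]
        seg_len = j - i
        mu = (s[j] - s[i]) / seg_len
        cost = (s2[j] - s2[i]) - seg_len * mu * mu
        cand = F[:j] + cost + beta
        arg = int(np.argmin(cand))
        F[j], prev[j] = cand[arg], arg
    splits = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            splits.append(i)
        j = i
    splits.reverse()
    return splits


def detect_breakpoints(
    series: np.ndarray,
    bin_size: int,
    penalty_scale: float = 3.0,
    min_sigma2: float = 1e-6,
) -> list[int]:
    """Candidate breakpoint positions (bp) from a penalised changepoint fit.

    Fits the non-missing bin values as a piecewise-constant series by exact
    dynamic programming, minimising total within-segment SSE plus a
    BIC-type penalty per split: penalty = penalty_scale * sigma^2 * log(n),
    with sigma estimated robustly from successive differences. Missing
    bins are skipped; a breakpoint between non-adjacent surviving bins maps
    to the midpoint of the missing gap.
    """
    y_all = np.asarray(series, dtype=float)
    obs = np.flatnonzero(~np.isnan(y_all))
    if obs.size < 2:
        if obs.size == 0:
            logger.warning("changepoint detection on an all-missing series")
        return []
    y = y_all[obs]
    n = y.size
    diffs = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0) if diffs.size else 0.0
    beta = penalty_scale * max(sigma * sigma, min_sigma2) * np.log(n)
    splits = _optimal_partition(y, beta)
    out = []
    for s in splits:
        left_bin, right_bin = obs[s - 1], obs[s]
        boundary = (left_bin + 1 + right_bin) / 2.0  # midpoint of any missing gap
        out.append(int(boundary * bin_size))
    return out


def detect_breakpoints_all(
    track: BinFrequencyTrack, **kwargs
) -> dict[tuple[str, str], list[int]]:
    """Breakpoint candidates per (individual, chrom)."""
    out: dict[tuple[str, str], list[int]] = {}
    for chrom, mat in track.freq.items():
        for i, ind in enumerate(track.individuals):
            bps = detect_breakpoints(mat[i], track.bin_size, **kwargs)
            if bps:
                out[(ind, chrom)] = bps
    return out


# ---------------------------------------------------------------------------
# two-state HMM with distance-scaled transitions


@numba.njit(cache=True)
def _forward_backward(le0, le1, switch):  # pragma: no cover - exercised via wrapper
    """Scaled forward-backward for 2 states; returns P(state 1) per site."""
    m = le0.shape[0]
    post = np.empty(m)
    alpha0 = np.empty(m)
    alpha1 = np.empty(m)
    b0 = np.empty(m)
    b1 = np.empty(m)
    for t in range(m):
        mx = le0[t] if le0[t] > le1[t] else le1[t]
        b0[t] = np.exp(le0[t] - mx)
        b1[t] = np.exp(le1[t] - mx)
    a0 = 0.5 * b0[0]
    a1 = 0.5 * b1[0]
    c = a0 + a1
    alpha0[0], alpha1[0] = a0 / c, a1 / c
    for t in range(1, m):
        sw = switch[t - 1]
        st = 1.0 - sw
        a0 = (alpha0[t - 1] * st + alpha1[t - 1] * sw) * b0[t]
        a1 = (alpha1[t - 1] * st + alpha0[t - 1] * sw) * b1[t]
        c = a0 + a1
        alpha0[t], alpha1[t] = a0 / c, a1 / c
    beta0 = 1.0
    beta1 = 1.0
    g0 = alpha0[m - 1] * beta0
    g1 = alpha1[m - 1] * beta1
    post[m - 1] = g1 / (g0 + g1)
    for t in range(m - 2, -1, -1):
        sw = switch[t]
        st = 1.0 - sw
        nb0 = st * b0[t + 1] * beta0 + sw * b1[t + 1] * beta1
        nb1 = st * b1[t + 1] * beta1 + sw * b0[t + 1] * beta0
        c = nb0 + nb1
        beta0, beta1 = nb0 / c, nb1 / c
        g0 = alpha0[t] * beta0
        g1 = alpha1[t] * beta1
        post[t] = g1 / (g0 + g1)
    return post


def switch_probability(distances: np.ndarray, tau: float) -> np.ndarray:
    """Per-interval switch probability a(d) = (1 - exp(-2 tau d)) / 2.

    The Haldane-style form keeps a(d) < 1/2 and makes tau the expected CO
    density per bp per gamete.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * tau * np.asarray(distances, dtype=float)))


def emission_loglik(
    alt: np.ndarray, depth: np.ndarray, error_eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood of read counts under HOM (p=eps) and HET (p=0.5).

    Zero-depth markers emit likelihood 1 in both states: they are
    uninformative, not dropped, so called intervals stay anchored to real
    marker coordinates.
    """
    alt = np.asarray(alt, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    if error_eps > 0:
        le_hom = stats.binom.logpmf(alt, depth, error_eps)
    else:
        with np.errstate(divide="ignore"):
            le_hom = np.where(alt == 0, 0.0, -np.inf)
    le_het = stats.binom.logpmf(alt, depth, 0.5)
    le_hom = np.where(depth == 0, 0.0, le_hom)
    le_het = np.where(depth == 0, 0.0, le_het)
    # keep -inf out of the scaled recursion; ~1e-300 in linear domain
    return np.maximum(le_hom, -690.0), np.maximum(le_het, -690.0)


def hmm_posterior(
    alt: np.ndarray, ref: np.ndarray, pos: np.ndarray, cfg: HmmConfig
) -> np.ndarray:
    """Posterior P(HET) per marker by forward-backward (uniform prior).

    Posteriors are normalised per marker (P(HOM) + P(HET) = 1); scaling in
    the recursion prevents underflow on long windows.
    """
    depth = np.asarray(alt) + np.asarray(ref)
    le_hom, le_het = emission_loglik(alt, depth, cfg.error_eps)
    sw = switch_probability(np.diff(np.asarray(pos, dtype=float)), cfg.switch_tau)
    return _forward_backward(
        np.ascontiguousarray(le_hom, dtype=np.float64),
        np.ascontiguousarray(le_het, dtype=np.float64),
        np.ascontiguousarray(sw, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# refinement of candidates into crossover events


def _events_from_posterior(
    post: np.ndarray, pos: np.ndarray, min_posterior: float
) -> list[tuple[int, int, int, int]]:
    """(left_idx, right_idx, state_left, state_right) per accepted flip.

    Flips are located where the decoded state (posterior > 0.5, exact ties
    skipped) changes; each flip is reported between the nearest flanking
    markers whose posterior for their side's state reaches min_posterior.
    Flips without a confident marker on both sides are rejected.
    """
    decided = np.flatnonzero(post != 0.5)
    if decided.size < 2:
        return []
    state = (post[decided] > 0.5).astype(np.int8)
    flips = np.flatnonzero(np.diff(state) != 0)
    conf_het = post >= min_posterior
    conf_hom = post <= 1.0 - min_posterior
    out = []
    for f in flips:
        i_left, i_right = decided[f], decided[f + 1]
        s_left, s_right = int(state[f]), int(state[f + 1])
        conf_left = conf_het if s_left == 1 else conf_hom
        conf_right = conf_het if s_right == 1 else conf_hom
        lcand = np.flatnonzero(conf_left[: i_left + 1])
        rcand = np.flatnonzero(conf_right[i_right:])
        if lcand.size == 0 or rcand.size == 0:
            continue
        li = int(lcand[-1])
        ri = int(rcand[0] + i_right)
        if pos[li] < pos[ri]:
            out.append((li, ri, s_left, s_right))
    return out


def refine_and_call(
    m: AlleleDepthMatrix,
    chrom_lengths: dict[str, int],
    candidates: dict[tuple[str, str], list[int]],
    cfg: HmmConfig | None = None,
    sex: str | None = None,
    pass_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refine candidate breakpoints into crossover events and genotype segments.

    For every candidate the HMM runs over retained SNPs in the window
    centred on it; all accepted flips in the window become events and
    duplicates from overlapping windows are merged. Candidates whose window
    decodes to a single state yield nothing.
    """
    cfg = cfg or HmmConfig()
    if pass_mask is None:
        pass_mask = m.markers.pass_mask
    ind_index = {ind: i for i, ind in enumerate(m.individuals)}
    half = cfg.window // 2
    ev_records: list[dict] = []
    seg_records: list[dict] = []
    seen: set[tuple[str, str, int, int]] = set()

    by_chrom: dict[str, list[tuple[str, list[int]]]] = {}
    for (ind, chrom), cands in candidates.items():
        by_chrom.setdefault(chrom, []).append((ind, cands))

    for chrom, entries in by_chrom.items():
        sl = m.markers.chrom_slice(chrom)
        keep = pass_mask[sl]
        pos = m.markers.table["pos"].to_numpy()[sl][keep]
        if pos.size == 0:
            continue
        alt_c = m.alt[:, sl][:, keep]
        ref_c = m.ref[:, sl][:, keep]
        for ind, cands in entries:
            row = ind_index[ind]
            flips_here: list[tuple[int, int, int, int]] = []
            for c in cands:
                lo = np.searchsorted(pos, max(0, c - half))
                hi = np.searchsorted(pos, c + half)
                if hi - lo < 1:
                    logger.warning("window at %s:%d has no covered marker", chrom, c)
                    continue
                post = hmm_posterior(
                    alt_c[row, lo:hi], ref_c[row, lo:hi], pos[lo:hi], cfg
                )
                for li, ri, s_l, s_r in _events_from_posterior(
                    post, pos[lo:hi], cfg.min_posterior
                ):
                    key = (ind, chrom, int(pos[lo + li]), int(pos[lo + ri]))
                    if key in seen:
                        continue
                    seen.add(key)
                    flips_here.append((lo + li, lo + ri, s_l, s_r))
                    ev_records.append(
                        {
                            "individual": ind,
                            "chrom": chrom,
                            "left_bp": int(pos[lo + li]),
                            "right_bp": int(pos[lo + ri]),
                            "midpoint": 0.0,
                            "resolution": 0,
                            "sex": sex,
                        }
                    )
            # chromosome-level alternating segments from the accepted flips
            flips_here.sort()
            bounds = [0] + [f[1] for f in flips_here] + [pos.size]
            if flips_here:
                states = [flips_here[0][2]]
                for f in flips_here:
                    states.append(f[3])
                for (b0, b1), st in zip(zip(bounds[:-1], bounds[1:]), states):
                    if b1 > b0:
                        seg_records.append(
                            {
                                "individual": ind,
                                "chrom": chrom,
                                "start_marker": int(b0),
                                "end_marker": int(b1),
                                "state": "HET" if st == 1 else "HOM",
                            }
                        )
    events = events_frame(ev_records)
    segments = pd.DataFrame(
        seg_records, columns=["individual", "chrom", "start_marker", "end_marker", "state"]
    )
    return segments, events


def estimate_switch_tau(n_events: int, n_individuals: int, genome_length: int) -> float:
    """Genome-wide CO density per bp per gamete (switch_tau re-estimate)."""
    if n_individuals <= 0 or genome_length <= 0:
        raise ValueError("need positive individuals and genome length")
    return max(n_events / (n_individuals * genome_length), 1e-12)


def call_crossovers(
    m: AlleleDepthMatrix,
    chrom_lengths: dict[str, int],
    cfg: HmmConfig | None = None,
    sex: str | None = None,
    bin_size: int = 200_000,
    pass_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full caller: bin -> segment -> HMM-refine, with switch_tau re-estimation.

    Runs tau_iterations rounds (default 2): call with the prior switch_tau,
    re-estimate it from the genome-wide call density, and call again. Returns
    (segments, events, diagnostics).
    """
    cfg = cfg or HmmConfig()
    track = bin_allele_frequency(m, chrom_lengths, bin_size, pass_mask)
    candidates = detect_breakpoints_all(track)
    diag: dict = {"n_candidates": sum(len(v) for v in candidates.values())}
    tau = cfg.switch_tau
    segments = events = None
    for it in range(cfg.tau_iterations):
        it_cfg = HmmConfig(
            window=cfg.window,
            error_eps=cfg.error_eps,
            switch_tau=tau,
            min_posterior=cfg.min_posterior,
            tau_iterations=cfg.tau_iterations,
        )
        segments, events = refine_and_call(
            m, chrom_lengths, candidates, it_cfg, sex=sex, pass_mask=pass_mask
        )
        new_tau = estimate_switch_tau(
            len(events), m.n_individuals, sum(chrom_lengths.values())
        )
        diag[f"tau_iter{it}"] = tau
        if abs(np.log(new_tau / tau)) < 1e-3:
            break
        tau = new_tau
    diag["n_events"] = len(events)
    return segments, events, diag


# ---------------------------------------------------------------------------
# bookkeeping statistics


def cos_per_meiosis(total_cos: int, n_individuals: int, ndigits: int | None = None) -> float:
    """COs per meiosis from gamete counts: 2 * total / n.

    Each BC1 individual carries one gamete, and a gamete receives on
    average half of its meiosis's crossovers, hence the factor 2. Pass
    ``ndigits`` for display rounding (the conventional report uses one
    decimal).
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if total_cos < 0:
        raise ValueError("total_cos must be >= 0")
    value = 2.0 * total_cos / n_individuals
    return round(value, ndigits) if ndigits is not None else value


def resolution_summary(
    events: pd.DataFrame, thresholds: tuple[int, ...] = (2_000,)
) -> dict:
    """Counts and fractions of COs mapped to within each resolution threshold.

    Reported overall and per sex (when the events carry sex labels).
    """
    if len(events) == 0:
        raise ValueError("no events to summarise")
    res = events["resolution"].to_numpy(dtype=float)
    out: dict = {"n_total": int(len(events)), "thresholds": {}}
    for t in thresholds:
        entry = {
            "n_le": int((res <= t).sum()),
            "fraction_le": float((res <= t).mean()),
        }
        if events["sex"].notna().any():
            entry["by_sex"] = {
                str(s): int((sub["resolution"] <= t).sum())
                for s, sub in events.groupby("sex")
            }
        out["thresholds"][int(t)] = entry
    return out
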