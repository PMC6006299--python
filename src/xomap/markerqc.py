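"""SNP retention filters applied to the allele-depth matrix before CO calling.

Three composable matrix-level filters mirror the genotyping screens such a
backcross design needs:

* allele frequency — a BC1 pools HOM (alt fraction ~= error rate) and HET
  (~0.5) individuals 50:50, so genuine markers show a population alt-read
  frequency near 0.25; sites outside [af_min, af_max] are mismapped or
  paralogous.
* linkage — a genuine marker's hard-called genotypes travel with its
  neighbours; the median Fisher-exact association p over up to K nearest
  markers in the same 10-Mbp interval must be below ld_alpha.
* depth — population-summed depth outside [dp_min, dp_max] flags
  copy-number artefacts (read pile-ups or dropouts).

A marker fails if any filter fails; all fail reasons are preserved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import fisher_exact_two_sided
from .config import FilterConfig
from .containers import AlleleDepthMatrix, MarkerSet

logger = logging.getLogger(__name__)

MISSING, CALL_HOM, CALL_HET = -1, 0, 1


def filter_allele_frequency(
    m: AlleleDepthMatrix, cfg: FilterConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Pass mask and no-data mask from the pooled alt-read frequency.

    The bounds are a closed interval (f == af_min passes). Markers with no
    covered read anywhere pass through, flagged separately as no-data.
    """
    f = m.pooled_alt_frequency()
    no_data = np.isnan(f)
    ok = no_data | ((f >= cfg.af_min) & (f <= cfg.af_max))
    return ok, no_data


def filter_depth(m: AlleleDepthMatrix, cfg: FilterConfig) -> np.ndarray:
    """Pass mask from the population-summed depth (inclusive bounds).

    When dp_min/dp_max are not set they default to dp_min_factor/
    dp_max_factor times the mean summed depth across markers.
    """
    dp = m.depth.sum(axis=0).astype(float)
    mean_dp = dp.mean() if dp.size else 0.0
    dp_min = cfg.dp_min if cfg.dp_min is not None else cfg.dp_min_factor * mean_dp
    dp_max = cfg.dp_max if cfg.dp_max is not None else cfg.dp_max_factor * mean_dp
    return (dp >= dp_min) & (dp <= dp_max)


def hard_calls(m: AlleleDepthMatrix) -> np.ndarray:
    """Per-(individual, marker) hard genotype calls for the linkage screen.

    Any alt read => HET, only ref reads => HOM, no reads => missing. Biased
    toward HOM at ~1.5x coverage (a HET site can show only ref reads), but
    adequate as a concordance screen; CO inference never uses hard calls.
    """
    calls = np.full(m.ref.shape, MISSING, dtype=np.int8)
    calls[m.ref > 0] = CALL_HOM
    calls[m.alt > 0] = CALL_HET
    return calls


def filter_ld(m: AlleleDepthMatrix, cfg: FilterConfig) -> np.ndarray:
    """Pass mask from the median Fisher-exact linkage p against neighbours.

    Markers are binned into ld_interval windows per chromosome. Each marker
    is paired with up to ld_neighbors nearest markers (by index) inside its
    window; for each pair a 2x2 genotype concordance table over individuals
    with both markers called feeds a two-sided Fisher exact test. Keep iff
    the median p < ld_alpha. Markers alone in their window (or with no
    evaluable pair) are kept by convention.
    """
    calls = hard_calls(m)
    tab = m.markers.table
    chrom_codes = pd.factorize(tab["chrom"])[0]
    interval = tab["pos"].to_numpy() // cfg.ld_interval
    group = chrom_codes * 10**7 + interval  # unique per (chrom, interval)

    n_markers = len(tab)
    half_k = max(1, cfg.ld_neighbors // 2)
    is_het = calls == CALL_HET
    observed = calls != MISSING

    p_sum_count: list[np.ndarray] = []
    pair_p = np.full((2 * half_k, n_markers), np.nan)
    row = 0
    for s in range(1, half_k + 1):
        if s >= n_markers:
            break
        same = group[:-s] == group[s:]
        a_het, b_het = is_het[:, :-s], is_het[:, s:]
        a_obs, b_obs = observed[:, :-s], observed[:, s:]
        both = a_obs & b_obs
        n11 = (a_het & b_het & both).sum(axis=0)
        n10 = (a_het & ~b_het & both).sum(axis=0)
        n01 = (~a_het & b_het & both).sum(axis=0)
        n00 = (~a_het & ~b_het & both).sum(axis=0)
        evaluable = same & ((n11 + n10 + n01 + n00) > 0)
        p = np.full(n_markers - s, np.nan)
        if evaluable.any():
            p[evaluable] = fisher_exact_two_sided(
                n11[evaluable], n10[evaluable], n01[evaluable], n00[evaluable]
            )
        # the pair (i, i+s) is a neighbour p for both ends
        pair_p[row, :-s] = p
        pair_p[row + 1, s:] = p
        row += 2

    with np.errstate(all="ignore"):
        med = np.nanmedian(pair_p, axis=0)
    no_pair = np.isnan(med)
    if no_pair.any():
        logger.warning("LD filter: %d markers had no evaluable pair; kept", int(no_pair.sum()))
    return no_pair | (med < cfg.ld_alpha)


def apply_filters(
    m: AlleleDepthMatrix, cfg: FilterConfig | None = None
) -> tuple[MarkerSet, dict]:
    """Run all filters; annotate the marker table with pass/fail_reasons.

    Returns the annotated MarkerSet and a summary dict of counts per fail
    reason (a marker may carry several reasons).
    """
    cfg = cfg or FilterConfig()
    af_ok, no_data = filter_allele_frequency(m, cfg)
    dp_ok = filter_depth(m, cfg)
    ld_ok = filter_ld(m, cfg)

    n = len(m.markers)
    reasons = [[] for _ in range(n)]
    for mask, name in ((~af_ok, "af"), (~dp_ok, "depth"), (~ld_ok, "ld")):
        for i in np.flatnonzero(mask):
            reasons[i].append(name)
    passed = af_ok & dp_ok & ld_ok

    table = m.markers.table.copy()
    table["pass"] = passed
    table["fail_reasons"] = [";".join(r) for r in reasons]
    table["no_data"] = no_data
    summary = {
        "n_markers": int(n),
        "n_pass": int(passed.sum()),
        "n_fail_af": int((~af_ok).sum()),
        "n_fail_depth": int((~dp_ok).sum()),
        "n_fail_ld": int((~ld_ok).sum()),
        "n_no_data": int(no_data.sum()),
    }
    logger.info("marker QC: %s", summary)
    return MarkerSet(table), summary
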