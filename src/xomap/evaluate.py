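"""Scoring called crossovers against simulated ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd


def match_events(
    truth: pd.DataFrame,
    events: pd.DataFrame,
    tolerance: float = 1_000_000.0,
    min_truth_spacing: float | None = None,
) -> dict:
    """Greedy one-to-one matching of called events to true CO positions.

    A call matches the nearest unmatched true CO of the same individual and
    chromosome within ``tolerance`` bp of its midpoint. Sensitivity is
    computed over eligible true COs (those at least ``min_truth_spacing``
    bp from their nearest same-gamete neighbour, when given); precision
    over all calls; containment is the fraction of matched calls whose
    [left_bp, right_bp) interval contains the true position.
    """
    truth = truth.copy()
    truth["matched"] = False
    truth["eligible"] = True
    if min_truth_spacing is not None:
        for (_, _), idx in truth.groupby(["individual", "chrom"]).groups.items():
            pos = truth.loc[idx, "pos"].to_numpy()
            if len(pos) > 1:
                order = np.argsort(pos)
                spacing = np.full(len(pos), np.inf)
                d = np.diff(pos[order])
                spacing[order[:-1]] = np.minimum(spacing[order[:-1]], d)
                spacing[order[1:]] = np.minimum(spacing[order[1:]], d)
                truth.loc[np.asarray(idx)[spacing < min_truth_spacing], "eligible"] = False

    n_matched_calls = 0
    n_contained = 0
    truth_groups = {
        key: sub.index.to_numpy() for key, sub in truth.groupby(["individual", "chrom"])
    }
    for _, ev in events.iterrows():
        key = (ev["individual"], ev["chrom"])
        idx = truth_groups.get(key)
        if idx is None:
            continue
        open_idx = idx[~truth.loc[idx, "matched"].to_numpy(dtype=bool)]
        if open_idx.size == 0:
            continue
        pos = truth.loc[open_idx, "pos"].to_numpy()
        d = np.abs(pos - ev["midpoint"])
        j = int(np.argmin(d))
        if d[j] <= tolerance:
            truth.loc[open_idx[j], "matched"] = True
            n_matched_calls += 1
            if ev["left_bp"] <= pos[j] < ev["right_bp"]:
                n_contained += 1

    eligible = truth["eligible"].to_numpy(dtype=bool)
    matched = truth["matched"].to_numpy(dtype=bool)
    n_calls = len(events)
    sens = float(matched[eligible].mean()) if eligible.any() else float("nan")
    prec = n_matched_calls / n_calls if n_calls else float("nan")
    containment = n_contained / n_matched_calls if n_matched_calls else float("nan")
    return {
        "n_true": int(len(truth)),
        "n_true_eligible": int(eligible.sum()),
        "n_calls": int(n_calls),
        "n_matched_calls": int(n_matched_calls),
        "sensitivity": sens,
        "precision": float(prec),
        "containment": float(containment),
    }
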