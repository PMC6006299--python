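"""End-to-end pipeline: simulate -> qc -> call -> map -> hotspots -> profiles.

Every stochastic stage receives a seed derived deterministically from the
global seed and the stage name, so a run is bit-reproducible from its
configuration alone. Stage outputs are written under ``out_dir`` together
with a machine-readable ``summary.json``.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import cocall, context, genmap, hotspot, io, markerqc, synthio
from .config import RunConfig, derive_seed
from .evaluate import match_events

logger = logging.getLogger(__name__)

SEXES = ("male", "female")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages on one simulated male and one female BC1 population.

    Returns the summary dict (also written to ``out_dir/summary.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = replace(cfg.sim, seed=derive_seed(cfg.seed, "sim"))
    chrom_lengths = sim.chrom_lengths

    markers = synthio.simulate_marker_set(sim)
    io.write_markers(markers, out / "markers.tsv")
    logger.info("simulated %d markers", len(markers))

    summary: dict = {
        "seed": int(cfg.seed),
        "n_markers": len(markers),
        "populations": {},
    }
    events_by_sex = {}
    truths = {}
    n_by_sex = {"male": cfg.n_male, "female": cfg.n_female}

    for sex in SEXES:
        pop = synthio.simulate_population(
            sim, n_by_sex[sex], sex=sex, markers=markers,
            seed_stream=derive_seed(cfg.seed, f"pop-{sex}") % (2**20),
        )
        truths[sex] = pop.truth
        if cfg.write_depths:
            io.write_depths(pop.depths, out / f"depths_{sex}.tsv")
        io.write_truth_bed(pop.truth.co, out / f"truth_{sex}.bed")

        flagged, qc_summary = markerqc.apply_filters(pop.depths, cfg.filters)
        segments, events, diag = cocall.call_crossovers(
            pop.depths,
            chrom_lengths,
            cfg.hmm,
            sex=sex,
            bin_size=cfg.bin_size,
            pass_mask=flagged.pass_mask,
        )
        io.write_events_bed(events, out / f"events_{sex}.bed")
        segments.to_csv(out / f"segments_{sex}.tsv", sep="\t", index=False)
        events_by_sex[sex] = events

        recovery = match_events(pop.truth.co, events, min_truth_spacing=1_000_000)
        res = (
            cocall.resolution_summary(events, thresholds=(cfg.resolution_threshold,))
            if len(events)
            else {"n_total": 0, "thresholds": {}}
        )
        summary["populations"][sex] = {
            "n_individuals": n_by_sex[sex],
            "qc": qc_summary,
            "n_candidates": diag["n_candidates"],
            "n_events": len(events),
            "cos_per_meiosis": cocall.cos_per_meiosis(
                len(events), n_by_sex[sex], ndigits=1
            ),
            "resolution": res,
            "recovery": recovery,
        }

    # genetic maps and male-female interval tests
    maps = {
        sex: genmap.interval_recombination(
            events_by_sex[sex], n_by_sex[sex], chrom_lengths, cfg.map_interval
        )
        for sex in SEXES
    }
    for sex in SEXES:
        maps[sex].to_csv(out / f"map_{sex}.tsv", sep="\t", index=False)
        genmap.marey_table(maps[sex]).to_csv(
            out / f"marey_{sex}.tsv", sep="\t", index=False
        )
    tests = genmap.sex_interval_tests(maps["male"], maps["female"])
    tests.to_csv(out / "interval_tests.tsv", sep="\t", index=False)
    summary["genetic_map"] = {
        "total_cm": {sex: float(maps[sex]["cm"].sum()) for sex in SEXES},
        "n_intervals": int(len(tests)),
        "n_significant_raw": int((tests["p"] < 0.05).sum()),
        "n_significant_bonferroni": int((tests["p_bonferroni"] < 0.05).sum()),
        "n_significant_bh": int((tests["p_bh"] < 0.05).sum()),
        "n_significant_by": int((tests["p_by"] < 0.05).sum()),
    }

    # hotspots
    windows = {
        sex: hotspot.window_rates(
            events_by_sex[sex], chrom_lengths, n_by_sex[sex],
            cfg.hotspot_window, cfg.hotspot_fold,
        )
        for sex in SEXES
    }
    shared = hotspot.shared_hotspot_stats(windows["male"], windows["female"])
    hs_summary = dict(shared)
    sites = hotspot.hotspot_site_rates(windows["male"], windows["female"])
    if len(sites) >= 10:
        try:
            boot = hotspot.bootstrap_correlation(
                sites, b=cfg.bootstrap_b,
                seed=np.random.default_rng(derive_seed(cfg.seed, "hotspot-boot")),
            )
            hs_summary["empirical_r"] = boot.empirical_r
            hs_summary["bootstrap_p_count"] = boot.p_count
            hs_summary["bootstrap_p_z"] = boot.p_z
        except ValueError as exc:
            hs_summary["bootstrap_error"] = str(exc)
    for sex in SEXES:
        flagged_w = windows[sex][windows[sex]["is_hotspot"]]
        flagged_w.to_csv(out / f"hotspots_{sex}.bed", sep="\t", index=False, header=False)
    summary["hotspots"] = hs_summary

    # annotations, tracks and profiles
    ann = synthio.simulate_annotations(sim)
    io.write_annotations_gff3(ann, out / "annotations.gff3")
    tracks = synthio.simulate_tracks(sim, truths)
    profiles: dict = {}
    for name, track in tracks.items():
        io.write_track_bedgraph(track, out / f"track_{name}.bedgraph")
        prof = {}
        for sex in SEXES:
            anchors = events_by_sex[sex].rename(columns={"midpoint": "pos"})[
                ["chrom", "pos"]
            ]
            if len(anchors) == 0:
                continue
            p = context.anchored_signal_profile(
                track, anchors, chrom_lengths, cfg.profile_flank, cfg.profile_bin
            )
            prof[sex] = p
            profiles[f"{name}_{sex}_peak_bp"] = p.peak
        if len(prof) == 2:
            test = context.profile_peak_test(
                prof["male"], prof["female"], n_boot=cfg.bootstrap_b,
                seed=np.random.default_rng(derive_seed(cfg.seed, f"peak-{name}")),
            )
            profiles[f"{name}_peak_delta_bp"] = test.delta_peak
            profiles[f"{name}_peak_p_z"] = test.p_z
    # CO density around gene starts
    for sex in SEXES:
        ev = events_by_sex[sex]
        if len(ev):
            dens = context.anchored_density_profile(
                ev.rename(columns={"midpoint": "pos"})[["chrom", "pos"]],
                ann.tss(), cfg.profile_flank, cfg.profile_bin,
            )
            profiles[f"tss_density_{sex}_peak_bp"] = dens.peak
            near = context.distance_to_nearest(
                ev.rename(columns={"midpoint": "pos"})[["chrom", "pos"]], ann.genes
            )["distance"].to_numpy()
            profiles[f"pct_within_10kb_of_gene_{sex}"] = 100.0 * context.fraction_within(
                near, 10_000
            )
    summary["profiles"] = profiles

    io.write_json(summary, out / "summary.json")
    return summary
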