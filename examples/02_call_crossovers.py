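"""Call crossovers from low-coverage depths and score them against truth.

The caller pools alt-read frequencies in 200-kbp bins, finds candidate
genotype breakpoints by changepoint segmentation, and refines each with a
two-state HMM over all SNPs in the surrounding 10-Mbp window. Reported
intervals run between the flanking markers whose genotype posterior is
confident (min_posterior), so the true exchange point lies inside the
interval with calibrated probability.
"""

from xomap import SimConfig, match_events
from xomap.cocall import call_crossovers, cos_per_meiosis
from xomap.markerqc import apply_filters
from xomap.synthio import simulate_gametes, simulate_marker_set, simulate_reads

cfg = SimConfig(
    chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000},
    co_per_meiosis_lambda=4.0,
    seed=2,
)
markers = simulate_marker_set(cfg)
gametes, truth = simulate_gametes(cfg, markers, 100)
depths = simulate_reads(gametes, cfg, markers)

flagged, qc = apply_filters(depths)
print(f"marker QC: {qc['n_pass']}/{qc['n_markers']} retained")

segments, events, diag = call_crossovers(
    depths, cfg.chrom_lengths, pass_mask=flagged.pass_mask
)
print(f"{diag['n_candidates']} segmentation candidates -> {len(events)} COs "
      f"({len(truth.co)} truly transmitted)")
print(f"estimated COs per meiosis: {cos_per_meiosis(len(events), 100, ndigits=1)} "
      f"(2 x calls / gametes; simulated at {cfg.co_per_meiosis_lambda})")

score = match_events(truth.co, events, min_truth_spacing=1_000_000)
print(f"sensitivity {score['sensitivity']:.3f}, precision {score['precision']:.3f}, "
      f"true CO inside called interval {100 * score['containment']:.1f}% of the time")
print(f"median interval width: {events['resolution'].median() / 1000:.1f} kbp")
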