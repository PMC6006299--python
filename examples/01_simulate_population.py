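"""Simulate a BC1 population and inspect its ground truth.

A backcross (F1 x recurrent parent) population is genotyped at ~1.5x
coverage; every individual carries one recombinant gamete whose crossovers
we will later try to recover. Here we build a small population and look at
what the generator recorded.
"""

import numpy as np

from xomap import SimConfig, simulate_marker_set, simulate_gametes, simulate_reads

cfg = SimConfig(
    chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
    co_per_meiosis_lambda=2.0,  # ~1 transmitted CO per gamete on this genome
    seed=1,
)
markers = simulate_marker_set(cfg)
gametes, truth = simulate_gametes(cfg, markers, n_individuals=50)
depths = simulate_reads(gametes, cfg, markers)

print(f"markers: {len(markers)} (~1 per kbp)")
print(f"individuals: 50; transmitted COs: {len(truth.co)} "
      f"(~{len(truth.co) / 50:.1f} per gamete, half the meiotic count)")
print(f"mean read depth per marker: {depths.depth.mean():.2f} "
      f"({100 * (depths.depth == 0).mean():.0f}% of entries have no read)")
f = depths.pooled_alt_frequency()
print(f"population alt-read frequency: median {np.nanmedian(f):.3f} "
      "(BC1 expectation ~0.25: half the individuals HET at 0.5)")
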