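# Methods

## Model and inference

### The observation model

A BC1 individual carries one recombinant gamete from the hybrid parent's
meiosis. At marker *j* its genotype is HOM (homozygous recurrent parent)
or HET, and the genotype sequence along a chromosome is piecewise
constant, switching at each transmitted crossover. Sequencing at mean
coverage λ gives, per (individual, marker), depth *n* ~ Poisson(λ) and
alt-read count *a* ~ Binomial(*n*, *p*) with *p* = ε under HOM (the
per-read miscall rate) and *p* = 0.5 under HET. At λ ≈ 1.5 most markers
have zero or one read, so no per-site genotype is callable and all
inference pools information along the chromosome.

### Marker QC

Three composable population-level filters flag markers before calling;
failing any one fails the marker and all reasons are retained:

* **Allele frequency**: pooled alt fraction in [0.1, 0.4], closed
  interval. A genuine BC1 marker pools ~half HET individuals at 0.5 and
  ~half HOM at ε, giving ~0.25; sites far from that are mismapped,
  paralogous, or monomorphic. Markers with no reads at all pass through
  flagged `no-data`.
* **Linkage**: markers are hard-called (any alt read → HET; only ref →
  HOM; no reads → missing) and each marker is tested for association
  against up to 20 nearest markers inside its 10-Mbp interval with a
  two-sided Fisher exact test on the 2×2 concordance table; keep iff the
  median p < 0.05. Hard calls are biased toward HOM at low coverage but
  adequate for a concordance screen; CO inference never uses them. The
  Fisher test is computed by a vectorised log-factorial routine (millions
  of pairs per population); it agrees with `scipy.stats.fisher_exact` to
  <1e-10 (tested). The screen needs ~100+ individuals to have power; with
  a few dozen individuals the per-pair p values cannot fall below ~0.05
  and the filter becomes conservative (it then removes markers that a
  larger population would keep, which wastes information but does not
  bias calls).
* **Depth**: population-summed depth within [dp_min, dp_max], defaulting
  to 0.5×/5× the mean summed depth. Collapsed repeats show up as pile-ups
  (and are also usually caught by the frequency filter); dropouts as
  near-zero depth.

### Crossover calling

1. **Binning**: per individual, alt/(alt+ref) pooled in non-overlapping
   200-kbp bins over retained markers; bins without reads are missing.
2. **Segmentation**: the non-missing bin series is fit piecewise-constant
   by exact dynamic programming minimising total within-segment SSE plus a
   penalty β per changepoint, β = 3·σ̂²·log n with σ̂ estimated robustly
   from successive differences (MAD/√2, floored at 1e-3 in SD units so a
   noise-free series still pays a positive penalty). The exact DP was
   chosen over approximate mean-shift segmentation because it is
   deterministic and oracle-testable: tests compare it against exhaustive
   single- and double-split search. The penalty is deliberately lenient —
   false candidates cost only HMM compute, missed candidates cost
   sensitivity — so candidate counts run several-fold above the true CO
   count.
3. **HMM refinement**: for each candidate, a two-state HMM runs over all
   retained SNPs in the 10-Mbp window centred on it. Emissions as above;
   zero-depth markers emit likelihood 1 in both states (uninformative but
   kept, so intervals stay anchored to real marker coordinates).
   Transitions between adjacent markers at distance d switch with
   a(d) = (1 − e^(−2τd))/2, the two-state analogue of the Haldane map,
   making τ the expected CO density per bp per gamete (default 5e-8 ≈ 10
   COs per 200-Mbp gamete). τ is re-estimated once from the genome-wide
   call density and calling repeated (2 rounds), which removes the
   circularity of fixing τ a priori. Posteriors come from scaled
   forward–backward (numba-compiled inner loop); they are normalised per
   marker and agree with exhaustive path enumeration to <1e-10 over
   hundreds of random configurations (tested).
4. **Event extraction**: a crossover is located where the decoded state
   (posterior > 0.5, exact ties skipped) flips. The reported interval runs
   from the last marker whose flanking-state posterior reaches
   `min_posterior` to the first such marker on the other side. With
   min_posterior = 0.999 each endpoint mislabels a true-state marker with
   odds roughly 2^-10 (each reference read on a HET marker contributes a
   factor ~2 toward HOM), so ≥99% of reported intervals contain the true
   exchange point — the property the interval is for. The cost is width:
   at 1.5x and 1 marker/kbp the median interval is ~10 kbp, wider than the
   raw flip-to-flip gap. A 0.5-crossing interval would look sharper but
   exclude the true CO in roughly a third of events at this coverage (the
   first HET marker beyond a crossover carries only reference reads with
   probability ~0.32), which we consider a miscalibrated report. Flips
   with no confident flanking marker on either side are rejected; this is
   also what suppresses clustered spurious-het "noise islands" from
   structural polymorphism, on top of the frequency filter that usually
   removes such markers outright. Duplicate events found from overlapping
   windows are merged by their marker interval.

Double crossovers inside one 200-kbp bin are invisible to segmentation
(the bin frequency returns to its flanking value); this is an accepted
limitation of the binned first pass. COs in the terminal part-bin of a
chromosome are detectable only through the partial frequency shift of
that bin and are occasionally missed.

### Landscape statistics

* **Genetic maps**: r = (recombinant individuals)/(total) per 1-Mbp
  interval by the CO-midpoint rule (an individual counts once per
  interval); Haldane d = −50 ln(1−2r) cM; Marey tables are cumulative cM
  per interval end. Interval boundaries are synthetic where no marker
  exists, so intervals are exact megabases. Physical marker order is
  taken from the reference; no linkage ordering is attempted.
* **Sex comparison**: per-interval likelihood-ratio (G) test of equal
  binomial proportions, df = 1; Bonferroni, Benjamini–Hochberg and
  Benjamini–Yekutieli families over all intervals.
* **Hotspots**: fixed non-overlapping 5-kbp windows (sliding windows
  would double-count shared "sites"); a window is a hotspot when its
  per-gamete CO rate is ≥5-fold the genome-average rate (inclusive) and
  it contains at least one CO. Sharing statistics are computed on the
  union of per-sex hotspot sets; the "top 10%" subset ranks sites by
  max(male fold, female fold). The bootstrap test resamples hotspot sites
  with replacement B=1000 times, recomputes the male–female Pearson rate
  correlation per replicate, and reports both the counting p (fraction of
  replicates above the empirical R) and its Gaussian analogue
  p_z = P(replicate > empirical) under a normal fit of the replicate
  distribution. Because the empirical value sits at the centre of its own
  bootstrap distribution, a representative R yields p ≈ 0.5 under either
  rule; values near 0 or 1 would indicate the site set is too small to
  characterise the correlation. Degenerate replicates (zero variance) are
  redrawn and logged.
* **Context**: CO–feature distances are 0 inside a feature and otherwise
  bp to the nearest covered base, signed strand-wise for genes (upstream
  negative). Enrichment against random placement uses a two-sided
  Mann–Whitney–Wilcoxon test on unsigned distances of uniformly placed
  points over the assembly (no mappability mask — the synthetic genome
  has none). Metaplots use ±2-kbp flanks in 50-bp bins (typical figure
  dimensions for such panels); profile peaks are the leftmost argmax
  after a 3-bin moving average, which stabilises bootstrap peak positions
  (a raw-argmax mode exists). The peak test resamples CO positions
  (density mode) or anchors (signal mode) B times per group and tests the
  replicate peak-difference distribution against 0, two-sided; under the
  null this Z is asymptotically standard normal, so p is uniform.
  Scaled-region profiles map each region to [0,1], average the track by
  exact piecewise integration per fractional bin, and weight regions
  equally; 100 bins by default, 30 for coarse tracks such as nucleosome
  occupancy.

## The synthetic generator

`synthio` emulates exactly the features the pipeline must survive:
Poisson marker placement at 1/kbp with optional polymorphism deserts;
per-meiosis CO counts Poisson(λ_CO·L_c/L_genome) per chromosome with each
CO transmitted to the sampled gamete with probability 1/2 (two of four
chromatids take part in any one crossover — the generative form of the
conventional ×2 per-meiosis conversion); CO positions from a
piecewise-constant intensity scaled by planted hotspot folds; Poisson
read depths with symmetric miscalls; clustered spurious-het noise regions
(alt bias and coverage multiplier) mimicking structural polymorphism; and
chromatin tracks as baseline plus Gaussian bumps (σ = 150 bp) at
configured offsets from true CO sites, per sex. Crossover interference is
off by default (a stationary gamma-renewal alternative sits behind
`interference_shape`; hotspot folds are ignored in that mode).

Defaults are the study conditions the package targets: 10 chromosomes ×
20 Mbp, 1 marker/kbp, coverage λ = 1.5, ε = 0.01, λ_CO = 20 per meiosis
(~10 transmitted per gamete). The genome is a scaled-down stand-in for a
maize-sized genome chosen so a full two-sex population runs on one CPU in
minutes; per-chromosome CO density (~1 per 20 Mbp per gamete) matches the
real design, so segmentation and HMM behaviour transfer. What the
generator does **not** emulate: alignment artefacts beyond the alt-bias
abstraction, GC/mappability coverage waves, marker-density
heterogeneity beyond explicit deserts, batch effects between
individuals, or genuine biological interference. Passing recovery tests
therefore demonstrates correctness of the inference given the stated
observation model, not robustness to every artefact of real data — the
QC filters and the confident-endpoint rule are the designed defences for
those, and the noise-region tests exercise them directly.

## Numerical choices and degenerate inputs

* Forward–backward uses per-site scaling (no underflow on 10k-marker
  windows); emission log-likelihoods are floored at −690 so ε = 0 stays
  finite.
* Changepoint DP: O(n²) exact optimisation per series (n ≈ 100 bins per
  chromosome); all-missing series yield no candidates with a warning.
* Posterior ties at exactly 0.5 are skipped when locating flips
  (conservative, widens the interval); profile-peak ties break leftmost
  and are deterministic.
* r ≥ 0.5 is a hard error in the Haldane transform (cannot arise from
  midpoint counting unless more than half the population recombines in
  one megabase — a data problem worth failing loudly on).
* Empty event sets: maps and Marey tables are flat zeros; hotspot grids
  flag nothing; resolution summaries refuse to summarise nothing.
* All randomness flows from `numpy.random.Generator` seeded per stage via
  SHA-256 of (global seed, stage name), below 2^31; identical
  configurations reproduce outputs bit-for-bit, including the pipeline's
  `summary.json`.

## Known limitations

* Reported interval widths are confidence intervals, not flip-to-flip
  gaps; they are several-fold wider than the narrowest defensible
  interval at 1.5x coverage. Raising coverage tightens them (tested:
  median width is non-increasing in λ).
* The LD screen is underpowered below ~100 individuals and then discards
  genuine markers (conservatively).
* Non-crossover events (gene conversion) and double COs within a bin are
  out of scope; no pedigree phasing.
* Hotspot detection needs enough COs that the 5-fold threshold exceeds a
  handful of events per window; at low totals single coincidental COs can
  clear the fold threshold, which is why the hotspot caller also requires
  a positive count and reports rates for inspection.
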