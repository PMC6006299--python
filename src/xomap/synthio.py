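"""Synthetic BC1 populations with known crossover ground truth.

The generator emulates the data a low-coverage backcross genotyping
experiment produces: an F1 hybrid is crossed back to the recurrent parent,
so every individual carries exactly one recombinant gamete and is, at each
marker, either homozygous parental (HOM) or heterozygous (HET) with 50:50
expectation. Reads are sampled per marker at Poisson coverage with a
symmetric per-read miscall rate. Polymorphism deserts, clustered
spurious-het noise regions (structural-polymorphism mimics), CO hotspots
and chromatin tracks with configurable peak offsets are all planted with
recorded ground truth so downstream stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import AlleleDepthMatrix, AnnotationSet, MarkerSet, SignalTrack

HOM, HET = 0, 1


@dataclass
class SimTruth:
    """Ground truth of one simulated population.

    ``co``: DataFrame (individual, chrom, pos) of transmitted CO positions
    (bp, strictly increasing per individual per chromosome).
    ``hotspots``: the planted intensity multipliers.
    ``track_offsets``: configured per-track peak offsets relative to CO sites.
    """

    co: pd.DataFrame
    hotspots: list = field(default_factory=list)
    track_offsets: dict[str, float] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_marker_set(config: SimConfig, rng: np.random.Generator | None = None) -> MarkerSet:
    """Sample SNP marker positions per chromosome at the configured density.

    Marker counts are Poisson(density * length); positions are uniform,
    deduplicated, sorted, and excluded from desert intervals. A chromosome
    left without markers (e.g. a desert covering it entirely) is an error.
    """
    rng = _rng(config, 0, rng)
    nucs = np.array(list("ACGT"))
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n = rng.poisson(config.marker_density * length / 1000.0)
        pos = np.unique(rng.integers(0, length, size=n))
        for c, s, e in config.desert_intervals:
            if c == chrom:
                pos = pos[(pos < s) | (pos >= e)]
        if pos.size == 0:
            raise ValueError(f"no informative markers left on {chrom}")
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": nucs[ref_idx], "alt": nucs[alt_idx]}
            )
        )
    return MarkerSet(pd.concat(frames, ignore_index=True))


def _intensity_segments(
    config: SimConfig, chrom: str, sex: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant CO intensity on one chromosome: (edges, fold per segment)."""
    L = config.chrom_lengths[chrom]
    cuts = {0, L}
    for h in config.hotspot_spec:
        if h.chrom == chrom and (h.sex is None or sex is None or h.sex == sex):
            cuts.add(max(0, min(L, h.start)))
            cuts.add(max(0, min(L, h.end)))
    edges = np.array(sorted(cuts), dtype=float)
    folds = np.ones(len(edges) - 1)
    for h in config.hotspot_spec:
        if h.chrom == chrom and (h.sex is None or sex is None or h.sex == sex):
            inside = (edges[:-1] >= h.start) & (edges[1:] <= h.end)
            folds[inside] *= h.fold
    return edges, folds


def _sample_positions(
    n: int, edges: np.ndarray, folds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    widths = np.diff(edges)
    mass = widths * folds
    total = mass.sum()
    if total <= 0 or n == 0:
        return np.empty(0)
    seg = rng.choice(len(mass), size=n, p=mass / total)
    return edges[seg] + rng.random(n) * widths[seg]


def _meiosis_co_count(
    lam: float, obligate: bool, rng: np.random.Generator
) -> int:
    n = rng.poisson(lam)
    if obligate and n == 0:
        n = 1
    return int(n)


def simulate_gametes(
    config: SimConfig,
    markers: MarkerSet,
    n_individuals: int,
    sex: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Simulate recombinant gametes of a BC1 population.

    Per meiosis and chromosome, the CO count is Poisson with mean
    proportional to the chromosome's intensity mass (base length times
    hotspot folds); each CO is independently transmitted to the sampled
    gamete with probability 1/2 (two of the four chromatids are involved in
    any given CO). The gamete's phase at the chromosome start is HOM or HET
    with equal probability; the genotype flips at every transmitted CO.

    Returns an int8 (n_individuals, n_markers) genotype matrix (0 = HOM,
    1 = HET) and the ground truth.
    """
    if len(markers) == 0:
        raise ValueError("markers must be nonempty")
    rng = _rng(config, 1, rng)
    genome = config.genome_length
    genos = np.empty((n_individuals, len(markers)), dtype=np.int8)
    records: list[dict] = []
    chrom_info = []
    for chrom in config.chrom_lengths:
        edges, folds = _intensity_segments(config, chrom, sex)
        lam_c = config.co_per_meiosis_lambda * config.chrom_lengths[chrom] / genome
        chrom_info.append((chrom, markers.chrom_slice(chrom), edges, folds, lam_c))

    for i in range(n_individuals):
        for chrom, sl, edges, folds, lam_c in chrom_info:
            if config.interference_shape is not None:
                # gamma-renewal process along the chromosome: gap shape k,
                # scale chosen so the expected CO count stays lam_c.
                # Hotspot folds are not applied under interference.
                L = config.chrom_lengths[chrom]
                k = config.interference_shape
                scale = L / max(lam_c, 1e-12) / k
                pts = []
                x = rng.gamma(k, scale)
                while x < L:
                    pts.append(x)
                    x += rng.gamma(k, scale)
                if config.obligate_co and not pts:
                    pts.append(rng.random() * L)
                pos_all = np.asarray(pts)
            else:
                n_meio = _meiosis_co_count(lam_c, config.obligate_co, rng)
                pos_all = np.sort(_sample_positions(n_meio, edges, folds, rng))
            n_meio = len(pos_all)
            transmitted = pos_all[rng.random(n_meio) < 0.5]
            start_state = int(rng.integers(0, 2))
            mpos = markers.table["pos"].to_numpy()[sl]
            parity = np.searchsorted(transmitted, mpos, side="right") % 2
            genos[i, sl] = (start_state + parity) % 2
            for p in transmitted:
                records.append({"individual": f"ind{i:04d}", "chrom": chrom, "pos": float(p)})

    truth = SimTruth(
        co=pd.DataFrame(records, columns=["individual", "chrom", "pos"]),
        hotspots=list(config.hotspot_spec),
        track_offsets={t.name: t.offset_bp for t in config.track_spec},
    )
    return genos, truth


def simulate_reads(
    gametes: np.ndarray,
    config: SimConfig,
    markers: MarkerSet,
    rng: np.random.Generator | None = None,
    individuals: list[str] | None = None,
) -> AlleleDepthMatrix:
    """Sample sparse read counts for each (individual, marker).

    Depth is Poisson(coverage_lambda); the alt-read probability is
    error_eps at HOM markers and 0.5 at HET markers. Noise regions override
    the alt probability with their alt_bias for every individual and scale
    coverage by coverage_mult.
    """
    rng = _rng(config, 2, rng)
    n_ind, m = gametes.shape
    lam = np.full(m, config.coverage_lambda)
    p_alt = np.where(gametes == HET, 0.5, config.error_eps)
    pos = markers.table["pos"].to_numpy()
    chrom_arr = markers.table["chrom"].to_numpy()
    for ns in config.noise_spec:
        in_region = (chrom_arr == ns.chrom) & (pos >= ns.start) & (pos < ns.end)
        lam = np.where(in_region, lam * ns.coverage_mult, lam)
        p_alt[:, in_region] = ns.alt_bias
    depth = rng.poisson(np.broadcast_to(lam, (n_ind, m)))
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    if individuals is None:
        individuals = [f"ind{i:04d}" for i in range(n_ind)]
    return AlleleDepthMatrix(
        individuals=individuals,
        ref=ref.astype(np.int32),
        alt=alt.astype(np.int32),
        markers=markers,
    )


def simulate_annotations(
    config: SimConfig, rng: np.random.Generator | None = None
) -> AnnotationSet:
    """Place gene models (with strand) and TE intervals along the genome.

    Starts follow a renewal process with exponential spacing; lengths are
    uniform in the configured range. Genes and TEs are placed independently
    of CO sites (context-module tests plant their own geometry).
    """
    rng = _rng(config, 3, rng)

    def _place(spacing: float, length_range: tuple[int, int]) -> pd.DataFrame:
        rows = []
        for chrom, L in config.chrom_lengths.items():
            x = 0.0
            while True:
                x += rng.exponential(spacing)
                ln = int(rng.integers(length_range[0], length_range[1] + 1))
                if x + ln >= L:
                    break
                rows.append((chrom, int(x), int(x) + ln))
                x += ln
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    genes = _place(config.gene_spacing, config.gene_length)
    genes["strand"] = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    genes["gene_id"] = [f"gene{i:05d}" for i in range(len(genes))]
    tes = _place(config.te_spacing, config.te_length)
    return AnnotationSet(genes=genes, tes=tes)


def simulate_tracks(
    config: SimConfig,
    truths: dict[str | None, SimTruth] | SimTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, SignalTrack]:
    """Build chromatin signal tracks: baseline + Gaussian bumps at CO + offset.

    Each TrackSpec entry adds bumps centred at (true CO position +
    offset_bp) for its population (``sex``; None uses every population in
    ``truths``). Entries sharing a name accumulate onto one track. With an
    empty track_spec the result is empty; a spec with no matching COs gives
    a flat baseline track.
    """
    if isinstance(truths, SimTruth):
        truths = {None: truths}
    step = config.track_step
    tracks: dict[str, SignalTrack] = {}
    for spec in config.track_spec:
        if spec.name not in tracks:
            tracks[spec.name] = SignalTrack(
                step=step,
                values={
                    c: np.full(int(np.ceil(L / step)), float(spec.baseline))
                    for c, L in config.chrom_lengths.items()
                },
            )
        track = tracks[spec.name]
        for sex, truth in truths.items():
            if spec.sex is not None and sex is not None and spec.sex != sex:
                continue
            for chrom, sub in truth.co.groupby("chrom"):
                v = track.values[chrom]
                centers = (np.arange(len(v)) + 0.5) * step
                for p in sub["pos"].to_numpy():
                    mu = p + spec.offset_bp
                    lo = max(0, int((mu - 5 * spec.width_bp) // step))
                    hi = min(len(v), int((mu + 5 * spec.width_bp) // step) + 1)
                    if hi > lo:
                        x = centers[lo:hi]
                        v[lo:hi] += spec.amplitude * np.exp(
                            -0.5 * ((x - mu) / spec.width_bp) ** 2
                        )
    return tracks


def simulate_annotations_and_tracks(
    config: SimConfig,
    truths: dict[str | None, SimTruth] | SimTruth,
    rng: np.random.Generator | None = None,
) -> tuple[AnnotationSet, dict[str, SignalTrack]]:
    return simulate_annotations(config, rng), simulate_tracks(config, truths, rng)


@dataclass
class PopulationSim:
    """Bundle of one simulated population: markers, gametes, truth, reads."""

    sex: str | None
    markers: MarkerSet
    gametes: np.ndarray
    truth: SimTruth
    depths: AlleleDepthMatrix


def simulate_population(
    config: SimConfig,
    n_individuals: int,
    sex: str | None = None,
    markers: MarkerSet | None = None,
    seed_stream: int = 10,
) -> PopulationSim:
    """Convenience wrapper: markers (shared if given) + gametes + reads."""
    if markers is None:
        markers = simulate_marker_set(config)
    from .config import derive_seed

    ss = np.random.SeedSequence(
        [int(config.seed), seed_stream, derive_seed(config.seed, f"pop:{sex}")]
    )
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    gametes, truth = simulate_gametes(config, markers, n_individuals, sex=sex, rng=r1)
    depths = simulate_reads(gametes, config, markers, rng=r2)
    return PopulationSim(sex=sex, markers=markers, gametes=gametes, truth=truth, depths=depths)
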