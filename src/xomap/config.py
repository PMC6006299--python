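"""Configuration dataclasses for simulation, QC, HMM inference and pipeline runs."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from a global seed and stage name."""
    h = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class HotspotSpec:
    """CO-intensity multiplier over [start, end) on one chromosome.

    ``fold`` scales the base per-bp CO intensity; ``sex`` restricts the
    multiplier to one population (None applies to both).
    """

    chrom: str
    start: int
    end: int
    fold: float
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.fold < 0:
            raise ValueError("hotspot fold must be >= 0")
        if self.end <= self.start:
            raise ValueError("hotspot interval must be non-empty")


@dataclass
class NoiseSpec:
    """Clustered spurious-heterozygous region mimicking structural polymorphism.

    Inside [start, end) the alt-read probability is forced to ``alt_bias``
    for every individual regardless of true genotype, and coverage is
    multiplied by ``coverage_mult`` (read pile-ups at collapsed repeats).
    """

    chrom: str
    start: int
    end: int
    alt_bias: float = 0.5
    coverage_mult: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_bias <= 1.0:
            raise ValueError("alt_bias must be in [0, 1]")


@dataclass
class TrackSpec:
    """One chromatin-track component: Gaussian bumps at (CO site + offset).

    ``offset_bp`` < 0 places the bump upstream of the CO site. ``sex``
    selects which population's true CO sites seed the bumps (None = all).
    Several entries may share a ``name``; their bumps add onto one track.
    """

    name: str
    offset_bp: float = 0.0
    sex: str | None = None
    amplitude: float = 2.0
    width_bp: float = 150.0
    baseline: float = 1.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic BC1 population generator.

    Defaults emulate the mapping design this pipeline targets: a maize-scale
    backcross genotyped at ~1.5x coverage with ~20 COs per meiosis (so ~10
    transmitted per gamete), one SNP marker per kbp, and a 1% per-read
    miscall rate. The genome is scaled down to 10 chromosomes x 20 Mbp so a
    full population fits in desk-scale compute.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 20_000_000 for i in range(1, 11)}
    )
    marker_density: float = 1.0  # mean markers per kbp
    desert_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    coverage_lambda: float = 1.5  # mean reads per marker per individual
    error_eps: float = 0.01  # per-read miscall probability
    co_per_meiosis_lambda: float = 20.0  # mean COs per meiosis per genome
    obligate_co: bool = False
    interference_shape: float | None = None  # gamma-renewal shape; None = Poisson process
    hotspot_spec: list[HotspotSpec] = field(default_factory=list)
    noise_spec: list[NoiseSpec] = field(default_factory=list)
    track_spec: list[TrackSpec] = field(default_factory=list)
    track_step: int = 50  # bp per signal-track bin
    gene_spacing: float = 25_000.0  # mean bp between gene starts
    gene_length: tuple[int, int] = (1_000, 5_000)
    te_spacing: float = 40_000.0
    te_length: tuple[int, int] = (500, 5_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.error_eps < 0.5:
            raise ValueError("error_eps must be in [0, 0.5)")
        if self.coverage_lambda <= 0:
            raise ValueError("coverage_lambda must be positive")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be positive")
        if self.co_per_meiosis_lambda < 0:
            raise ValueError("co_per_meiosis_lambda must be >= 0")

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class FilterConfig:
    """SNP retention filters applied before CO inference.

    Markers are kept when the population alt-read frequency lies in
    [af_min, af_max] (a BC1 expects ~0.25: half the individuals HET at 0.5),
    the median Fisher-exact linkage p against nearby markers in the same
    ld_interval is below ld_alpha, and the population-summed depth lies in
    [dp_min, dp_max]. dp bounds default to dp_min_factor/dp_max_factor times
    the mean summed depth when not set explicitly.
    """

    af_min: float = 0.1
    af_max: float = 0.4
    ld_interval: int = 10_000_000
    ld_alpha: float = 0.05
    ld_neighbors: int = 20  # nearest in-interval markers tested per site
    dp_min: float | None = None
    dp_max: float | None = None
    dp_min_factor: float = 0.5
    dp_max_factor: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_min < self.af_max <= 1.0:
            raise ValueError("require 0 <= af_min < af_max <= 1")
        if self.ld_interval <= 0 or self.ld_neighbors < 1:
            raise ValueError("invalid LD filter parameters")


@dataclass
class HmmConfig:
    """Two-state (HOM/HET) genotype HMM over SNPs around a candidate breakpoint.

    Emissions are Binomial(alt; depth, p) with p = error_eps for HOM and 0.5
    for HET; the per-interval switch probability for inter-marker distance d
    is a(d) = (1 - exp(-2*switch_tau*d))/2, i.e. switch_tau is the expected
    CO density per bp per gamete. Reported CO intervals run from the last
    marker whose flanking-state posterior reaches min_posterior to the first
    marker on the other side doing the same; flips without such confident
    flanks are rejected (this is what suppresses structural-polymorphism
    noise islands).
    """

    window: int = 10_000_000
    error_eps: float = 0.01
    switch_tau: float = 5e-8
    min_posterior: float = 0.999
    tau_iterations: int = 2  # call -> re-estimate switch_tau -> recall

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_eps < 0.5:
            raise ValueError("error_eps must be in [0, 0.5)")
        if not 0.0 < self.switch_tau < 0.5:
            raise ValueError("switch_tau must be in (0, 0.5)")
        if not 0.5 < self.min_posterior < 1.0:
            raise ValueError("min_posterior must be in (0.5, 1)")
        if self.tau_iterations < 1:
            raise ValueError("tau_iterations must be >= 1")


def default_sim_config() -> SimConfig:
    """Default study conditions including the sex-offset chromatin geometry
    (male open-chromatin peak ~250 bp upstream of CO sites, female at them)."""
    return SimConfig(
        track_spec=[
            TrackSpec("h3k4me3", -250.0, "male"),
            TrackSpec("h3k4me3", 0.0, "female"),
        ]
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> qc -> call -> map ->
    hotspots -> profiles)."""

    seed: int = 0
    out_dir: str = "xomap_run"
    sim: SimConfig = field(default_factory=default_sim_config)
    filters: FilterConfig = field(default_factory=FilterConfig)
    hmm: HmmConfig = field(default_factory=HmmConfig)
    n_male: int = 135
    n_female: int = 122
    bin_size: int = 200_000
    map_interval: int = 1_000_000
    hotspot_window: int = 5_000
    hotspot_fold: float = 5.0
    profile_flank: int = 2_000
    profile_bin: int = 50
    bootstrap_b: int = 1000
    resolution_threshold: int = 2_000
    write_depths: bool = False  # full sparse depth TSVs are large; opt in

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict):
    return cls(**data)


def run_config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a plain (YAML/JSON-loaded) mapping."""
    data = dict(data)
    if "sim" in data:
        sim = dict(data["sim"])
        sim["hotspot_spec"] = [HotspotSpec(**h) for h in sim.get("hotspot_spec", [])]
        sim["noise_spec"] = [NoiseSpec(**h) for h in sim.get("noise_spec", [])]
        sim["track_spec"] = [TrackSpec(**h) for h in sim.get("track_spec", [])]
        if "gene_length" in sim:
            sim["gene_length"] = tuple(sim["gene_length"])
        if "te_length" in sim:
            sim["te_length"] = tuple(sim["te_length"])
        data["sim"] = SimConfig(**sim)
    if "filters" in data:
        data["filters"] = FilterConfig(**data["filters"])
    if "hmm" in data:
        data["hmm"] = HmmConfig(**data["hmm"])
    return RunConfig(**data)
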