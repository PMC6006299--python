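"""Core in-memory containers shared by all pipeline stages.

Coordinates are 0-based half-open internally; file readers/writers in
:mod:`xomap.io` convert at the boundary (marker TSV and GFF3 are 1-based
on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MarkerSet:
    """Ordered SNP markers, one row per marker.

    ``table`` columns: ``chrom`` (str), ``pos`` (int, 0-based), ``ref``,
    ``alt`` (single nucleotides). QC adds boolean ``pass`` and string
    ``fail_reasons`` columns. Positions are strictly increasing within a
    chromosome and (chrom, pos) pairs are unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("empty marker set")
        for _, sub in self.table.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of a chromosome's markers."""
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    @property
    def pass_mask(self) -> np.ndarray:
        if "pass" in self.table.columns:
            return self.table["pass"].to_numpy(dtype=bool)
        return np.ones(len(self.table), dtype=bool)


@dataclass
class AlleleDepthMatrix:
    """Per-individual (ref, alt) read counts for every marker.

    ``ref`` and ``alt`` are (n_individuals, n_markers) integer arrays
    aligned to ``markers.table`` rows. Most entries are zero-depth at the
    low coverage this pipeline targets (~1.5x).
    """

    individuals: list[str]
    ref: np.ndarray
    alt: np.ndarray
    markers: MarkerSet

    def __post_init__(self) -> None:
        n, m = len(self.individuals), len(self.markers)
        if self.ref.shape != (n, m) or self.alt.shape != (n, m):
            raise ValueError(
                f"depth arrays must have shape ({n}, {m}); got {self.ref.shape}, {self.alt.shape}"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read depths must be non-negative")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def pooled_alt_frequency(self) -> np.ndarray:
        """Population alt-read frequency per marker; NaN where uncovered."""
        alt = self.alt.sum(axis=0).astype(float)
        tot = alt + self.ref.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)


@dataclass
class SignalTrack:
    """Fixed-step binned genome signal (e.g. H3K4me3, nucleosome occupancy).

    ``values[chrom][i]`` covers [i*step, (i+1)*step). NaN marks missing bins.
    """

    step: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("track step must be positive")
        self._cum: dict[str, np.ndarray] = {}

    def _cumulative(self, chrom: str) -> np.ndarray:
        # prefix integral of the step function, NaN treated as 0 signal
        if chrom not in self._cum:
            v = np.nan_to_num(self.values[chrom], nan=0.0)
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(v) * self.step])
        return self._cum[chrom]

    def integral(self, chrom: str, start: float, end: float) -> float:
        """Exact integral of the step function over [start, end)."""
        v = self.values[chrom]
        L = len(v) * self.step
        start, end = max(0.0, start), min(float(L), end)
        if end <= start:
            return 0.0
        cum = self._cumulative(chrom)
        i0, i1 = int(start // self.step), int(end // self.step)
        if i0 == i1:
            x = v[i0]
            return float((0.0 if np.isnan(x) else x) * (end - start))
        total = cum[i1] - cum[i0 + 1]
        x0 = v[i0]
        total += (0.0 if np.isnan(x0) else x0) * ((i0 + 1) * self.step - start)
        if i1 < len(v):
            x1 = v[i1]
            total += (0.0 if np.isnan(x1) else x1) * (end - i1 * self.step)
        return float(total)

    def mean(self, chrom: str, start: float, end: float) -> float:
        if end <= start:
            return float("nan")
        return self.integral(chrom, start, end) / (end - start)


@dataclass
class AnnotationSet:
    """Gene and TE annotations plus labelled special regions.

    ``genes``: DataFrame (chrom, start, end, strand, gene_id); TSS/TTS are
    derived from strand (TSS = start for '+', end-1 for '-').
    ``tes``: DataFrame (chrom, start, end).
    ``regions``: named interval lists (knobs, chromosome ends, centromeres)
    as DataFrames (chrom, start, end).
    """

    genes: pd.DataFrame
    tes: pd.DataFrame
    regions: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        if len(g) and not set(g["strand"]).issubset({"+", "-"}):
            raise ValueError("gene strand must be '+' or '-'")
        if len(g) and (g["end"] <= g["start"]).any():
            raise ValueError("gene intervals must be non-empty")

    def tss(self) -> pd.DataFrame:
        """Anchor table (chrom, pos, strand) of transcription start sites."""
        g = self.genes
        pos = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        return pd.DataFrame({"chrom": g["chrom"], "pos": pos, "strand": g["strand"]})

    def tts(self) -> pd.DataFrame:
        """Anchor table of transcription termination sites."""
        g = self.genes
        pos = np.where(g["strand"] == "+", g["end"] - 1, g["start"])
        return pd.DataFrame({"chrom": g["chrom"], "pos": pos, "strand": g["strand"]})


EVENT_COLUMNS = ["individual", "chrom", "left_bp", "right_bp", "midpoint", "resolution", "sex"]


def events_frame(records: list[dict] | None = None) -> pd.DataFrame:
    """Canonical crossover-event table.

    One row per CO: interval [left_bp, right_bp) between the flanking
    confidently-genotyped markers, midpoint = (left+right)/2, resolution =
    right - left, sex label of the population.
    """
    df = pd.DataFrame(records or [], columns=EVENT_COLUMNS)
    if len(df):
        if (df["left_bp"] >= df["right_bp"]).any():
            raise ValueError("event left_bp must be < right_bp")
        df["midpoint"] = (df["left_bp"] + df["right_bp"]) / 2.0
        df["resolution"] = df["right_bp"] - df["left_bp"]
    return df
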