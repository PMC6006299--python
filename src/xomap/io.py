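"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open; conversions happen here and
only here. Marker TSV and GFF3 are 1-based on disk; BED and bedGraph are
0-based half-open. All writers produce deterministic byte-identical output
for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig, run_config_from_dict
from .containers import AlleleDepthMatrix, AnnotationSet, MarkerSet, SignalTrack, events_frame


class FormatError(ValueError):
    """Malformed record, with file and line context."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# markers and depths (TSV)


def write_markers(markers: MarkerSet, path) -> None:
    t = markers.table.copy()
    t["pos"] = t["pos"] + 1  # 1-based on disk
    t.to_csv(path, sep="\t", index=False)


def read_markers(path) -> MarkerSet:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    t["pos"] = t["pos"] - 1
    return MarkerSet(t)


def write_depths(m: AlleleDepthMatrix, path) -> None:
    """Sparse long-format depth table; zero-depth entries are omitted.

    A header comment preserves the full individual roster (individuals may
    have no covered marker at very low coverage).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#individuals=" + ",".join(m.individuals) + "\n")
        fh.write("individual\tchrom\tpos\tref_depth\talt_depth\n")
        tab = m.markers.table
        chrom = tab["chrom"].to_numpy()
        pos = tab["pos"].to_numpy()
        for i, ind in enumerate(m.individuals):
            nz = np.flatnonzero((m.ref[i] > 0) | (m.alt[i] > 0))
            for j in nz:
                fh.write(f"{ind}\t{chrom[j]}\t{pos[j] + 1}\t{m.ref[i, j]}\t{m.alt[i, j]}\n")


def read_depths(path, markers: MarkerSet) -> AlleleDepthMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#individuals="):
        raise FormatError(path, 1, "missing #individuals= header")
    individuals = first.split("=", 1)[1].split(",")
    df = pd.read_csv(path, sep="\t", comment="#")
    key = {
        (c, p): j
        for j, (c, p) in enumerate(zip(markers.table["chrom"], markers.table["pos"]))
    }
    ind_idx = {ind: i for i, ind in enumerate(individuals)}
    ref = np.zeros((len(individuals), len(markers)), dtype=np.int32)
    alt = np.zeros_like(ref)
    for lineno, row in enumerate(df.itertuples(index=False), start=3):
        j = key.get((row.chrom, row.pos - 1))
        if j is None:
            raise FormatError(path, lineno, f"unknown marker {row.chrom}:{row.pos}")
        i = ind_idx.get(row.individual)
        if i is None:
            raise FormatError(path, lineno, f"unknown individual {row.individual}")
        ref[i, j] = row.ref_depth
        alt[i, j] = row.alt_depth
    return AlleleDepthMatrix(individuals=individuals, ref=ref, alt=alt, markers=markers)


# ---------------------------------------------------------------------------
# crossover events (BED, 0-based half-open)


def write_events_bed(events: pd.DataFrame, path) -> None:
    """chrom, left_bp, right_bp, individual, resolution, sex."""
    with open(path, "w") as fh:
        for _, e in events.iterrows():
            fh.write(
                f"{e['chrom']}\t{int(e['left_bp'])}\t{int(e['right_bp'])}"
                f"\t{e['individual']}\t{int(e['resolution'])}\t{e['sex'] or '.'}\n"
            )


def read_events_bed(path) -> pd.DataFrame:
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(path, lineno, f"expected 6 fields, got {len(parts)}")
            try:
                chrom, left, right, ind, res, sex = (
                    parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]), parts[5],
                )
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad field: {exc}") from exc
            if right <= left:
                raise FormatError(path, lineno, "interval end must exceed start")
            records.append(
                {
                    "individual": ind,
                    "chrom": chrom,
                    "left_bp": left,
                    "right_bp": right,
                    "midpoint": 0.0,
                    "resolution": res,
                    "sex": None if sex == "." else sex,
                }
            )
    return events_frame(records)


def write_truth_bed(truth_co: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in truth_co.iterrows():
            p = int(r["pos"])
            fh.write(f"{r['chrom']}\t{p}\t{p + 1}\t{r['individual']}\n")


# ---------------------------------------------------------------------------
# annotations (GFF3, 1-based closed)


def write_annotations_gff3(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in ann.genes.iterrows():
            fh.write(
                f"{g['chrom']}\txomap\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )
        for i, t in ann.tes.iterrows():
            fh.write(
                f"{t['chrom']}\txomap\ttransposable_element\t{t['start'] + 1}\t{t['end']}"
                f"\t.\t.\t.\tID=te{i:05d}\n"
            )


def read_annotations_gff3(path) -> AnnotationSet:
    path = Path(path)
    genes, tes = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(path, lineno, f"expected 9 fields, got {len(parts)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad coordinate: {exc}") from exc
            if ftype == "gene":
                gene_id = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                ).get("ID", f"gene_at_{chrom}_{start}")
                genes.append((chrom, start0, end0, strand, gene_id))
            elif ftype == "transposable_element":
                tes.append((chrom, start0, end0))
    return AnnotationSet(
        genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"]),
        tes=pd.DataFrame(tes, columns=["chrom", "start", "end"]),
    )


# ---------------------------------------------------------------------------
# signal tracks (bedGraph, 0-based half-open)


def write_track_bedgraph(track: SignalTrack, path) -> None:
    """Adjacent equal-valued bins are merged into runs."""
    with open(path, "w") as fh:
        for chrom in track.values:
            v = track.values[chrom]
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [v.size]])
            for s, e in zip(starts, ends):
                if np.isnan(v[s]):
                    continue
                fh.write(
                    f"{chrom}\t{s * track.step}\t{e * track.step}\t{v[s]:.6g}\n"
                )


def read_track_bedgraph(path, step: int, chrom_lengths: dict[str, int]) -> SignalTrack:
    """Read a bedGraph into fixed-step bins; overlapping records are an error."""
    path = Path(path)
    values = {
        c: np.full(int(np.ceil(L / step)), np.nan) for c, L in chrom_lengths.items()
    }
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(path, lineno, f"expected 4 fields, got {len(parts)}")
            chrom, s, e, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom in last_end and s < last_end[chrom]:
                raise FormatError(path, lineno, "overlapping bedGraph intervals")
            last_end[chrom] = e
            if chrom not in values:
                continue
            if s % step or e % step:
                raise FormatError(path, lineno, f"interval not aligned to step {step}")
            values[chrom][s // step : e // step] = val
    return SignalTrack(step=step, values=values)


# ---------------------------------------------------------------------------
# configs and reports


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def write_json(data: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
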