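"""Readers and writers for the formats the pipeline touches.

GFF3 coordinates are 1-based inclusive on disk and converted to the
package-internal 0-based half-open convention on read; BED and bedGraph are
0-based half-open in both places. Floats are written with 6 significant
digits.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import GENE_TYPES, EnrichedRegion, EnrichmentTrack, GeneModel, ProbeTrack

__all__ = [
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "write_regions_bed",
    "read_regions_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_signal_table",
    "read_signal_table",
    "write_coverage_bedgraph",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]
_FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: PathLike) -> list[GeneModel]:
    """Parse gene features from a GFF3 file into GeneModel records.

    Expects a ``gene_type`` attribute; records with an unknown type are
    downgraded to ``other_RNA`` with a warning. Malformed lines raise with
    their line number.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID", f"gene_{lineno}")
            gene_type = attr_map.get("gene_type", "other_RNA")
            if gene_type not in GENE_TYPES:
                logger.warning("%s:%d: unknown gene_type %r -> other_RNA", path, lineno, gene_type)
                gene_type = "other_RNA"
            te_class = attr_map.get("te_class") if gene_type == "transposon" else None
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                    end=end_i,
                    strand=strand,
                    gene_type=gene_type,
                    te_class=te_class,
                )
            )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};gene_type={g.gene_type}"
            if g.te_class is not None:
                attrs += f";te_class={g.te_class}"
            fh.write(
                f"{g.chrom}\ttilemark\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path: PathLike) -> list[tuple[str, int, int]]:
    """Plain intervals from the first three BED columns."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Sequence[tuple[str, int, int]], path: PathLike) -> None:
    _check_sorted([(c, s, e) for c, s, e in intervals])
    with open(path, "w") as fh:
        if not intervals:
            fh.write("# empty\n")
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_regions_bed(regions: Sequence[EnrichedRegion], path: PathLike) -> None:
    """Enriched regions as BED6; score = round(1000 * mean posterior)."""
    _check_sorted([(r.chrom, r.start, r.end) for r in regions])
    with open(path, "w") as fh:
        if not regions:
            fh.write("# empty\n")
        for i, r in enumerate(regions, start=1):
            score = int(round(1000 * r.mean_posterior))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i:05d}\t{score}\t.\n")


def read_regions_bed(path: PathLike) -> list[EnrichedRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            posterior = int(f[4]) / 1000.0 if len(f) >= 5 else 1.0
            out.append(
                EnrichedRegion(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    mean_posterior=min(posterior, 1.0), n_probes=1,
                )
            )
    return out


def _check_sorted(intervals: Sequence[tuple[str, int, int]]) -> None:
    for prev, cur in zip(intervals, intervals[1:]):
        if cur[0] == prev[0] and cur[1] < prev[1]:
            raise ValueError("intervals must be sorted by start within each chromosome")


def write_bedgraph(track: EnrichmentTrack, path: PathLike, span: int = 35) -> None:
    """Probe points expanded to [pos, pos + span) intervals, one line each."""
    with open(path, "w") as fh:
        if track.n_probes == 0:
            fh.write("# empty\n")
        for pos, val in zip(track.positions, track.value):
            end = pos + span
            fh.write(f"{track.chrom}\t{pos}\t{end}\t{_fmt(val)}\n")


def read_bedgraph(path: PathLike) -> EnrichmentTrack:
    chroms, positions, values = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chroms.append(f[0])
            positions.append(int(f[1]))
            values.append(float(f[3]))
    if not positions:
        return EnrichmentTrack("chr1", np.array([], dtype=np.int64), np.array([]))
    if len(set(chroms)) > 1:
        raise ValueError("read_bedgraph expects a single-chromosome file")
    return EnrichmentTrack(chroms[0], np.array(positions), np.array(values))


def write_coverage_bedgraph(coverage: dict[str, np.ndarray], window_bp: int, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, vals in coverage.items():
            for i, v in enumerate(vals):
                fh.write(f"{chrom}\t{i * window_bp}\t{(i + 1) * window_bp}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# Signal tables


def write_signal_table(
    layout: np.ndarray,
    experiment: dict[str, dict[str, np.ndarray]],
    path: PathLike,
    chrom: str = "chr1",
) -> None:
    """TSV with chrom, position, then one column per mark/channel/replicate.

    Column names look like ``me2.ip.r1``.
    """
    data = {"chrom": [chrom] * len(layout), "position": np.asarray(layout, dtype=np.int64)}
    for mark, channels in experiment.items():
        for channel, mat in channels.items():
            mat = np.atleast_2d(mat)
            for rep in range(mat.shape[1]):
                data[f"{mark}.{channel}.r{rep + 1}"] = mat[:, rep]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_signal_table(path: PathLike, strict: bool = True) -> dict[tuple[str, str], ProbeTrack]:
    """Per-(mark, channel) ProbeTracks from a signal TSV.

    With ``strict`` (default) unsorted or duplicate positions raise; with
    ``strict=False`` rows are sorted by position first (duplicates still
    raise).
    """
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns or "position" not in df.columns:
        raise ValueError(f"{path}: signal table needs 'chrom' and 'position' columns")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("read_signal_table expects a single-chromosome table")
    pos = df["position"].to_numpy(dtype=np.int64)
    if pd.Series(pos).duplicated().any():
        raise ValueError(f"{path}: duplicate probe positions")
    if not np.all(np.diff(pos) > 0):
        if strict:
            raise ValueError(f"{path}: probe positions are not sorted (use strict=False to sort)")
        df = df.sort_values("position").reset_index(drop=True)
        pos = df["position"].to_numpy(dtype=np.int64)
    groups: dict[tuple[str, str], list[str]] = {}
    for col in df.columns:
        if col in ("chrom", "position"):
            continue
        parts = col.split(".")
        if len(parts) != 3:
            raise ValueError(f"{path}: cannot parse signal column name {col!r}")
        groups.setdefault((parts[0], parts[1]), []).append(col)
    tracks = {}
    for (mark, channel), cols in groups.items():
        cols = sorted(cols, key=lambda c: int(c.rsplit("r", 1)[1]))
        tracks[(mark, channel)] = ProbeTrack(str(chroms[0]), pos, df[cols].to_numpy(dtype=float))
    return tracks
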