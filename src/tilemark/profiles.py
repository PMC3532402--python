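"""Fixed 15-bin genic positional profiles.

The window scheme per gene, in transcription orientation:

* 3 promoter windows of 100 bp each covering -350..-50 relative to the TSS
* 1 TSS window from -50 bp to 5% of the transcribed length
* 9 gene-body windows of 10% each, from 5% to 95%
* 1 three-prime-end window from 95% to +50 bp beyond the gene end
* 1 three-prime-flank window from +50 to +150 bp beyond the gene end

Minus-strand genes use the mirror image of the plus-strand windows so that
bin 1 is always promoter-proximal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import EnrichmentTrack, GeneModel

__all__ = [
    "BIN_LABELS",
    "PositionalProfile",
    "gene_windows",
    "select_spaced_genes",
    "positional_profile",
    "profile_matrix",
    "group_mean_profile",
    "decile_profiles",
    "relative_profile",
]

logger = logging.getLogger(__name__)

BIN_LABELS = ("P1", "P2", "P3", "TSS", "B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B9", "E", "F")
N_BINS = len(BIN_LABELS)
MIN_GENE_LENGTH = 20


@dataclass
class PositionalProfile:
    gene_id: str
    bins: np.ndarray  # 15 values, NaN where a window holds no probe

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float).ravel()
        if self.bins.size != N_BINS:
            raise ValueError(f"a positional profile must have exactly {N_BINS} bins")


def gene_windows(gene: GeneModel) -> list[tuple[int, int]]:
    """The 15 half-open genomic windows for a gene, promoter-first."""
    s, e = gene.start, gene.end
    length = e - s
    if length < MIN_GENE_LENGTH:
        raise ValueError(f"gene {gene.gene_id} shorter than {MIN_GENE_LENGTH} bp")
    # proportional boundaries at 5%, 15%, ..., 95% of the transcribed length
    bounds = [s + (length * (5 + 10 * k)) // 100 for k in range(10)]
    windows = [(s - 350, s - 250), (s - 250, s - 150), (s - 150, s - 50), (s - 50, bounds[0])]
    windows += [(bounds[k], bounds[k + 1]) for k in range(9)]
    windows += [(bounds[9], e + 50), (e + 50, e + 150)]
    if gene.strand == "-":
        # mirror each window about the gene; bin order stays promoter-first
        windows = [(s + e - b, s + e - a) for a, b in windows]
    return windows


def select_spaced_genes(
    genes: Sequence[GeneModel], min_5prime: int = 350, min_3prime: int = 150
) -> list[GeneModel]:
    """Keep genes whose neighbors are far enough away on both genic sides.

    Distances are boundary-to-boundary in transcription orientation; a gene
    with no neighbor on one side passes that side automatically.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept: list[GeneModel] = []
    for chrom_genes in by_chrom.values():
        chrom_genes = sorted(chrom_genes, key=lambda g: (g.start, g.end))
        for i, g in enumerate(chrom_genes):
            left = g.start - chrom_genes[i - 1].end if i > 0 else None
            right = chrom_genes[i + 1].start - g.end if i + 1 < len(chrom_genes) else None
            up, down = (left, right) if g.strand == "+" else (right, left)
            ok_5 = up is None or up >= min_5prime
            ok_3 = down is None or down >= min_3prime
            if ok_5 and ok_3:
                kept.append(g)
    kept.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return kept


def positional_profile(track: EnrichmentTrack, gene: GeneModel) -> Optional[PositionalProfile]:
    """Mean track value per window; windows without probes are NaN.

    Returns None (with a logged warning) for genes shorter than the minimum
    transcribed length, and for genes on another chromosome than the track.
    """
    if gene.length < MIN_GENE_LENGTH:
        logger.warning("skipping gene %s: transcribed length %d < %d bp", gene.gene_id, gene.length, MIN_GENE_LENGTH)
        return None
    if gene.chrom != track.chrom:
        logger.warning("skipping gene %s: not on track chromosome %s", gene.gene_id, track.chrom)
        return None
    bins = np.full(N_BINS, np.nan)
    pos = track.positions
    for i, (a, b) in enumerate(gene_windows(gene)):
        lo = int(np.searchsorted(pos, a, side="left"))
        hi = int(np.searchsorted(pos, b, side="left"))
        if hi > lo:
            bins[i] = float(track.value[lo:hi].mean())
    return PositionalProfile(gene.gene_id, bins)


def profile_matrix(track: EnrichmentTrack, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Profiles for many genes as a genes x 15 frame (skipped genes omitted)."""
    rows, ids = [], []
    for g in genes:
        prof = positional_profile(track, g)
        if prof is not None:
            rows.append(prof.bins)
            ids.append(prof.gene_id)
    return pd.DataFrame(rows, index=ids, columns=list(BIN_LABELS))


def group_mean_profile(profiles: pd.DataFrame, groups: Mapping[str, object]) -> pd.DataFrame:
    """Per-group per-bin mean over non-missing values."""
    if profiles.empty:
        raise ValueError("cannot average an empty profile set (empty group)")
    assigned = pd.Series({gid: groups[gid] for gid in profiles.index})
    out = {}
    for label in sorted(set(assigned), key=str):
        members = profiles.loc[assigned[assigned == label].index]
        if members.empty:
            raise ValueError(f"group {label!r} is empty")
        out[label] = members.mean(axis=0, skipna=True)
    return pd.DataFrame(out).T[list(BIN_LABELS)]


def decile_profiles(profiles: pd.DataFrame, expression: Mapping[str, float]) -> pd.DataFrame:
    """Ten mean profiles for genes ranked by expression (decile 1 = lowest).

    Genes split into 10 equal bins; when the count is not divisible by 10 the
    remainder goes to the lower deciles. Ties are broken by gene id so the
    assignment is deterministic.
    """
    n = len(profiles)
    if n < 10:
        raise ValueError("decile profiles require at least 10 genes")
    order = sorted(profiles.index, key=lambda gid: (expression[gid], gid))
    base, rem = divmod(n, 10)
    groups: dict[str, int] = {}
    i = 0
    for d in range(1, 11):
        size = base + (1 if d <= rem else 0)
        for gid in order[i : i + size]:
            groups[gid] = d
        i += size
    return group_mean_profile(profiles, groups)


def relative_profile(profile_a: pd.DataFrame, profile_b: pd.DataFrame) -> pd.DataFrame:
    """Bin-wise difference a - b on a shared gene/bin schema; NaN propagates."""
    if not profile_a.columns.equals(profile_b.columns) or not profile_a.index.equals(profile_b.index):
        raise ValueError("profiles must share gene index and bin schema")
    return profile_a - profile_b
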