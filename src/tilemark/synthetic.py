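"""Synthetic data generators.

Everything the analysis chain consumes can be simulated at desk scale:
a non-overlapping gene annotation with a configurable type mix and a
pericentromeric heterochromatin block, a regularly spaced probe layout,
linear-scale IP/input signal matrices with planted enriched regions, and
a tissue-expression matrix spanning uniform to one-hot specificity.

Every generator is a pure function of its configuration and seed.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import GENE_TYPES, TE_CLASSES, GeneModel, SimulationConfig

__all__ = [
    "allocate_counts",
    "generate_annotation",
    "generate_probe_layout",
    "generate_chip_experiment",
    "generate_expression",
]


def allocate_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer counts per category: floor(fraction * n) plus largest-remainder top-up.

    Remainder ties are broken by the canonical gene-type order, so the
    allocation is deterministic.
    """
    order = [t for t in GENE_TYPES if t in fractions] + [t for t in fractions if t not in GENE_TYPES]
    raw = {t: fractions[t] * n for t in order}
    counts = {t: int(np.floor(raw[t])) for t in order}
    short = n - sum(counts.values())
    by_remainder = sorted(order, key=lambda t: (-(raw[t] - counts[t]), order.index(t)))
    for t in by_remainder[:short]:
        counts[t] += 1
    return counts


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[tuple[str, int, int]]]:
    """Non-overlapping genes sorted by coordinate plus heterochromatin intervals.

    Genes are laid left to right with random lengths and intergenic gaps; a
    single heterochromatin block of ``het_fraction`` of the genome is centred
    on the genome midpoint (the designated "centromere"). Transposon genes
    are preferentially assigned to positions inside heterochromatin with
    weight ``te_het_enrichment``.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    rng = np.random.default_rng(config.seed)
    glo, ghi = config.gene_length_range
    ilo, ihi = config.intergenic_gap_range
    lengths = rng.integers(glo, ghi + 1, size=config.n_genes)
    gaps = rng.integers(max(ilo, 1), ihi + 1, size=config.n_genes)
    needed = int(lengths.sum() + gaps.sum())
    if needed > config.genome_length_bp:
        raise ValueError(
            f"genome of {config.genome_length_bp} bp too short to place "
            f"{config.n_genes} non-overlapping genes (need {needed} bp); "
            "increase genome_length_bp or reduce n_genes/gene lengths"
        )
    coords = []
    pos = 0
    for L, gap in zip(lengths, gaps):
        pos += int(gap)
        coords.append((pos, pos + int(L)))
        pos += int(L)
    # stretch placements across the full genome so het/eu both hold genes
    stretch = (config.genome_length_bp - 1) / max(pos, 1)
    if stretch > 1.0:
        scaled = []
        for s, e in coords:
            off = int(s * (stretch - 1.0))
            scaled.append((s + off, e + off))
        coords = scaled

    mid = config.genome_length_bp // 2
    half = int(config.het_fraction * config.genome_length_bp / 2)
    het_intervals = [(config.chrom, mid - half, mid + half)] if half > 0 else []

    counts = allocate_counts(config.gene_type_fractions, config.n_genes)
    midpoints = np.array([(s + e) // 2 for s, e in coords])
    in_het = np.zeros(config.n_genes, dtype=bool)
    for _, hs, he in het_intervals:
        in_het |= (midpoints >= hs) & (midpoints < he)

    gene_types = np.empty(config.n_genes, dtype=object)
    available = np.arange(config.n_genes)
    n_te = counts.get("transposon", 0)
    if n_te > 0:
        w = np.where(in_het[available], config.te_het_enrichment, 1.0)
        te_idx = rng.choice(available, size=n_te, replace=False, p=w / w.sum())
        gene_types[te_idx] = "transposon"
        available = np.setdiff1d(available, te_idx)
    rng.shuffle(available)
    cursor = 0
    for t in GENE_TYPES:
        if t == "transposon":
            continue
        c = counts.get(t, 0)
        gene_types[available[cursor : cursor + c]] = t
        cursor += c

    strands = rng.choice(["+", "-"], size=config.n_genes)
    te_class_probs = np.array([0.25, 0.25, 0.2, 0.3])  # LINE/L1, Copia, Gypsy, other
    genes = []
    for i, (s, e) in enumerate(coords):
        te_class = None
        if gene_types[i] == "transposon":
            te_class = str(rng.choice(TE_CLASSES, p=te_class_probs))
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:05d}",
                chrom=config.chrom,
                start=s,
                end=e,
                strand=str(strands[i]),
                gene_type=str(gene_types[i]),
                te_class=te_class,
            )
        )
    genes.sort(key=lambda g: (g.start, g.end))
    return genes, het_intervals


def generate_probe_layout(genome_length_bp: int, probe_spacing_bp: int = 35) -> np.ndarray:
    """Probe point positions 0, s, 2s, ... strictly below the genome length."""
    if probe_spacing_bp <= 0:
        raise ValueError("probe spacing must be positive")
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    return np.arange(0, genome_length_bp, probe_spacing_bp, dtype=np.int64)


def generate_chip_experiment(
    layout: np.ndarray,
    planted_regions: Sequence[tuple],
    config: SimulationConfig,
) -> dict[str, dict[str, np.ndarray]]:
    """Linear-scale IP and input matrices (probes x replicates) per mark.

    Input values are ``2 ** (baseline + noise)``; IP values inside a planted
    region additionally carry that region's ``effect_log2`` before
    exponentiation. The H3 channel carries a smooth occupancy structure
    independent of the marks (also present in mark IPs, so H3 adjustment
    removes it). A configurable fraction of probes is flipped to
    non-positive values to exercise downstream flooring.
    """
    layout = np.asarray(layout, dtype=np.int64)
    n = layout.size
    marks = list(config.marks)
    for chrom, start, end, mark, effect in planted_regions:
        if chrom != config.chrom:
            raise ValueError(f"planted region references unknown chromosome {chrom!r}")
        if mark not in marks:
            raise ValueError(f"planted region references unknown mark {mark!r}")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(marks) + 1)
    occ_rng = np.random.default_rng(children[-1])
    if config.h3_occupancy_amp > 0:
        phase = occ_rng.uniform(0, 2 * np.pi)
        occupancy = config.h3_occupancy_amp * np.sin(2 * np.pi * layout / 50_000.0 + phase)
    else:
        occupancy = np.zeros(n)

    out: dict[str, dict[str, np.ndarray]] = {}
    for mark, child in zip(marks, children):
        rng = np.random.default_rng(child)
        effect = np.zeros(n)
        if mark != "H3":
            for chrom, start, end, m, eff in planted_regions:
                if m == mark:
                    effect[(layout >= start) & (layout < end)] += eff
        shape = (n, config.n_replicates)
        input_log2 = config.baseline_mean + rng.normal(0.0, config.noise_sd, size=shape)
        ip_log2 = (
            config.baseline_mean
            + occupancy[:, None]
            + effect[:, None]
            + rng.normal(0.0, config.noise_sd, size=shape)
        )
        ip_lin = np.exp2(ip_log2)
        input_lin = np.exp2(input_log2)
        if config.frac_nonpositive > 0:
            for mat in (ip_lin, input_lin):
                k = int(round(config.frac_nonpositive * mat.size))
                if k:
                    flat = rng.choice(mat.size, size=k, replace=False)
                    mat.flat[flat] = -np.abs(rng.normal(0.0, 1.0, size=k))
        out[mark] = {"ip": ip_lin, "input": input_lin}
    return out


def generate_expression(
    genes: Sequence[GeneModel],
    n_tissues: int,
    specificity_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x tissues non-negative expression matrix.

    Each gene follows one archetype drawn from ``specificity_mix``:
    ``uniform`` (equal across tissues), ``onehot`` (all signal in one
    tissue), ``sparse`` (Dirichlet-concentrated), or ``silent`` (all zero).
    """
    if n_tissues < 2:
        raise ValueError("need at least two tissues")
    mix = specificity_mix or {"uniform": 0.4, "onehot": 0.2, "sparse": 0.3, "silent": 0.1}
    if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("specificity_mix must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    archetypes = list(mix)
    probs = np.array([mix[a] for a in archetypes])
    rows = []
    for g in genes:
        arch = rng.choice(archetypes, p=probs)
        level = float(rng.lognormal(mean=3.0, sigma=1.0))
        if arch == "uniform":
            row = np.full(n_tissues, level)
        elif arch == "onehot":
            row = np.zeros(n_tissues)
            row[rng.integers(n_tissues)] = level * n_tissues
        elif arch == "sparse":
            row = level * n_tissues * rng.dirichlet(np.full(n_tissues, 0.3))
        elif arch == "silent":
            row = np.zeros(n_tissues)
        else:
            raise ValueError(f"unknown archetype {arch!r}")
        rows.append(row)
    cols = [f"tissue_{i + 1}" for i in range(n_tissues)]
    return pd.DataFrame(rows, index=[g.gene_id for g in genes], columns=cols)
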