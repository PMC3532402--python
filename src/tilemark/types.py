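"""Shared domain types for the tiling-array ChIP pipeline.

All genomic coordinates are 0-based half-open throughout the package;
conversion to/from 1-based inclusive happens only at the GFF3 boundary
(see :mod:`tilemark.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Gene-type vocabulary, in the display order used by the summary tables.
GENE_TYPES = (
    "protein_coding",
    "transposon",
    "pseudogene",
    "tRNA",
    "other_RNA",
    "miRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
)

#: Transposable-element superfamily vocabulary.
TE_CLASSES = ("LINE/L1", "LTR/Copia", "LTR/Gypsy", "other")


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: half-open interval, strand, type and optional TE class."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_type: str
    te_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"gene {self.gene_id}: unknown gene_type {self.gene_type!r}")
        if self.te_class is not None and self.gene_type != "transposon":
            raise ValueError(f"gene {self.gene_id}: te_class is only valid for transposon genes")
        if self.te_class is not None and self.te_class not in TE_CLASSES:
            raise ValueError(f"gene {self.gene_id}: unknown te_class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def tss(self) -> int:
        """Transcription start boundary (gene start for '+', gene end for '-')."""
        return self.start if self.strand == "+" else self.end


@dataclass
class ProbeTrack:
    """Ordered probe positions with a probes x replicates value matrix for one channel."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.positions.shape[0]:
            # allow a (reps, probes) matrix passed transposed by mistake only if unambiguous
            raise ValueError(
                f"values has {self.values.shape[0]} rows but there are "
                f"{self.positions.shape[0]} probe positions"
            )
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")

    @property
    def n_probes(self) -> int:
        return int(self.positions.size)

    @property
    def n_replicates(self) -> int:
        return int(self.values.shape[1])


@dataclass
class EnrichmentTrack:
    """Single per-probe log2 enrichment value (IP/input, optionally H3-adjusted)."""

    chrom: str
    positions: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float).ravel()
        if self.value.shape[0] != self.positions.shape[0]:
            raise ValueError("value length must match number of positions")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("enrichment values must be finite")

    @property
    def n_probes(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class EnrichedRegion:
    """A genomic interval called enriched, with its mean posterior and probe count."""

    chrom: str
    start: int
    end: int
    mean_posterior: float
    n_probes: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if not (0.0 <= self.mean_posterior <= 1.0):
            raise ValueError("mean_posterior must lie in [0, 1]")
        if self.n_probes < 1:
            raise ValueError("a region must contain at least one probe")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HMMConfig:
    """Parameters of the two-state enriched-region caller."""

    max_gap_bp: int = 1000
    min_run_bp: int = 200
    posterior_cutoff: float = 0.5
    stay_prob_background: float = 0.99
    stay_prob_enriched: float = 0.9
    em_max_iter: int = 50
    em_tol: float = 1e-4
    variance_shrinkage_weight: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior_cutoff <= 1.0):
            raise ValueError("posterior_cutoff must lie in [0, 1]")
        if self.min_run_bp <= 0:
            raise ValueError("min_run_bp must be positive")
        if self.max_gap_bp < 0:
            raise ValueError("max_gap_bp must be non-negative")
        for name in ("stay_prob_background", "stay_prob_enriched"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must lie strictly within (0, 1)")
        if not (0.0 <= self.variance_shrinkage_weight <= 1.0):
            raise ValueError("variance_shrinkage_weight must lie in [0, 1]")


def _default_gene_type_fractions() -> dict:
    # mirrors a realistic genome-wide gene-type mix (mostly protein-coding,
    # ~12% transposon-related, few per-cent small-RNA/pseudogene)
    return {
        "protein_coding": 0.819,
        "transposon": 0.118,
        "pseudogene": 0.026,
        "tRNA": 0.019,
        "other_RNA": 0.010,
        "miRNA": 0.005,
        "snoRNA": 0.002,
        "snRNA": 0.0004,
        "rRNA": 0.0006,
    }


@dataclass
class SimulationConfig:
    """Configuration for the synthetic annotation / ChIP-signal / expression generators."""

    seed: int = 0
    genome_length_bp: int = 1_000_000
    probe_spacing_bp: int = 35
    n_replicates: int = 2
    n_genes: int = 200
    gene_type_fractions: dict = field(default_factory=_default_gene_type_fractions)
    planted_regions: Sequence = field(default_factory=list)
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    n_tissues: int = 8
    chrom: str = "chr1"
    marks: Sequence[str] = ("me2", "me3", "H3")
    het_fraction: float = 0.2
    te_het_enrichment: float = 4.0
    frac_nonpositive: float = 0.01
    h3_occupancy_amp: float = 0.3
    gene_length_range: tuple = (500, 3000)
    intergenic_gap_range: tuple = (200, 800)

    def __post_init__(self) -> None:
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        total = sum(self.gene_type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gene_type_fractions must sum to 1 (got {total!r})")
        for t in self.gene_type_fractions:
            if t not in GENE_TYPES:
                raise ValueError(f"unknown gene type in fractions: {t!r}")
        for reg in self.planted_regions:
            chrom, start, end, mark, effect = reg
            if end <= start:
                raise ValueError(f"planted region {reg}: end must exceed start")
        if not (0.0 <= self.het_fraction < 1.0):
            raise ValueError("het_fraction must lie in [0, 1)")
        if not (0.0 <= self.frac_nonpositive < 1.0):
            raise ValueError("frac_nonpositive must lie in [0, 1)")
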