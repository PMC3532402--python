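"""Region-to-gene linkage and gene-type enrichment statistics.

A gene counts as enriched when any part of its annotated transcribed
region overlaps an enriched region by at least one base; promoter-only
overlap does not count. Per-type representation tables use two-sided
Fisher exact tests; set overlap between two marks uses a chi-square
test of independence without continuity correction.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .types import GENE_TYPES, TE_CLASSES, EnrichedRegion, GeneModel

__all__ = [
    "link_regions_to_genes",
    "gene_type_table",
    "set_overlap_test",
    "stratified_enrichment",
    "long_region_composition",
    "assign_strata",
]

FOCAL_TE_CLASSES = ("LINE/L1", "LTR/Copia", "LTR/Gypsy")


def link_regions_to_genes(
    regions: Sequence[EnrichedRegion], genes: Sequence[GeneModel]
) -> np.ndarray:
    """Boolean flag per gene: True iff some region overlaps its transcribed span >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        # prefix max of ends lets us answer "any interval with start < x and end > y"
        index[chrom] = (starts, np.maximum.accumulate(ends))
    flags = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        if g.chrom not in index:
            continue
        starts, cummax_ends = index[g.chrom]
        j = int(np.searchsorted(starts, g.end, side="left"))  # regions with start < g.end
        flags[i] = j > 0 and cummax_ends[j - 1] > g.start
    return flags


def _fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]]."""
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def gene_type_table(flags: Sequence[bool], genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-type representation among all genes and among enriched genes.

    Returns a frame indexed by gene type with counts, percentages, the
    two-sided Fisher exact p of (type vs other) x (enriched vs not), an
    over/under direction, and a Bonferroni-corrected p column.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(genes):
        raise ValueError("flags and genes must have equal length")
    types = np.array([g.gene_type for g in genes])
    n_total = len(genes)
    n_enr = int(flags.sum())
    rows = []
    for t in GENE_TYPES:
        is_t = types == t
        count_entire = int(is_t.sum())
        count_enr = int((is_t & flags).sum())
        a = count_enr
        b = n_enr - count_enr
        c = count_entire - count_enr
        d = (n_total - count_entire) - b
        p = 1.0 if n_enr == 0 else _fisher_2x2(a, b, c, d)
        pct_entire = 100.0 * count_entire / n_total if n_total else 0.0
        pct_enr = 100.0 * count_enr / n_enr if n_enr else 0.0
        rows.append(
            {
                "gene_type": t,
                "count_entire": count_entire,
                "pct_entire": pct_entire,
                "count_enriched": count_enr,
                "pct_enriched": pct_enr,
                "fisher_p": p,
                "direction": "over" if pct_enr > pct_entire else "under",
                "bonferroni_p": min(1.0, p * len(GENE_TYPES)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_type")


def set_overlap_test(flags_a: Sequence[bool], flags_b: Sequence[bool]) -> dict:
    """Observed vs expected overlap of two enriched-gene sets on one universe.

    Expected overlap under independence is N * p_A * p_B; significance comes
    from a chi-square test of independence on the 2x2 cross-classification,
    continuity correction off.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must share the gene universe")
    n = a.size
    if n == 0:
        raise ValueError("empty gene universe")
    observed = int((a & b).sum())
    expected = n * a.mean() * b.mean()
    table = np.array(
        [
            [observed, int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p = 1.0
    else:
        p = float(chi2_contingency(table, correction=False)[1])
    return {"observed_overlap": observed, "expected_overlap": float(expected), "chi_square_p": p}


def assign_strata(
    genes: Sequence[GeneModel], het_intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """True where a gene's midpoint falls inside a (half-open) heterochromatin interval."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in het_intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    in_het = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        mid = g.midpoint
        in_het[i] = any(s <= mid < e for s, e in by_chrom.get(g.chrom, ()))
    return in_het


def stratified_enrichment(
    flags: Sequence[bool],
    genes: Sequence[GeneModel],
    het_intervals: Sequence[tuple[str, int, int]],
) -> dict[str, pd.DataFrame]:
    """gene_type_table computed separately for heterochromatin and euchromatin."""
    flags = np.asarray(flags, dtype=bool)
    in_het = assign_strata(genes, het_intervals)
    out = {}
    for name, mask in (("heterochromatin", in_het), ("euchromatin", ~in_het)):
        sub_genes = [g for g, m in zip(genes, mask) if m]
        out[name] = gene_type_table(flags[mask], sub_genes) if sub_genes else pd.DataFrame()
    return out


def long_region_composition(
    regions: Sequence[EnrichedRegion],
    genes: Sequence[GeneModel],
    min_len: int = 1000,
    size_band: tuple[int, int] = (1000, 4000),
    focal_classes: Sequence[str] = FOCAL_TE_CLASSES,
) -> dict:
    """TE-class makeup of genes under long regions vs size-matched background.

    Restricts to regions of length >= ``min_len``, tabulates the te_class of
    overlapped transposon genes, and Fisher-tests focal classes against the
    composition of all transposon genes whose length falls in ``size_band``.
    """
    long_regions = [r for r in regions if r.length >= min_len]
    if not long_regions:
        return {"composition": {}, "background_composition": {}, "fisher_p": None}
    te_genes = [g for g in genes if g.gene_type == "transposon"]
    overlapped = link_regions_to_genes(long_regions, te_genes)
    comp: dict[str, int] = {c: 0 for c in TE_CLASSES}
    for g, hit in zip(te_genes, overlapped):
        if hit:
            comp[g.te_class or "other"] += 1
    lo, hi = size_band
    band = [(g, h) for g, h in zip(te_genes, overlapped) if lo <= g.length <= hi]
    bg: dict[str, int] = {c: 0 for c in TE_CLASSES}
    for g, _ in band:
        bg[g.te_class or "other"] += 1
    focal = set(focal_classes)
    in_long_focal = sum(1 for g, h in band if h and (g.te_class in focal))
    in_long_other = sum(1 for g, h in band if h and (g.te_class not in focal))
    out_focal = sum(1 for g, h in band if not h and (g.te_class in focal))
    out_other = sum(1 for g, h in band if not h and (g.te_class not in focal))
    total = in_long_focal + in_long_other + out_focal + out_other
    p = _fisher_2x2(in_long_focal, in_long_other, out_focal, out_other) if total else None
    return {
        "composition": {c: n for c, n in comp.items() if n},
        "background_composition": {c: n for c, n in bg.items() if n},
        "fisher_p": p,
    }
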