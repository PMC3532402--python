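"""Multi-mark profile clustering and expression/entropy summaries."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterResult",
    "concat_and_cluster",
    "shannon_entropy",
    "expression_summary",
    "expression_group_summary",
]


@dataclass
class ClusterResult:
    gene_ids: list[str]
    assignments: np.ndarray  # labels in 1..k
    centroids: np.ndarray  # k x (n_bins * n_marks)
    within_cluster_ss: float
    k: int
    seed: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.assignments, index=self.gene_ids, name="cluster")


def concat_and_cluster(
    profile_sets: Sequence[pd.DataFrame],
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_missing_frac: float = 0.5,
    minmax_scale: bool = False,
) -> ClusterResult:
    """K-means on per-gene concatenated multi-mark positional profiles.

    All profile frames must share the same gene index. Genes with more than
    ``max_missing_frac`` missing bins (over the concatenation) are dropped;
    remaining missing bins are imputed with 0, the neutral value on the log2
    relative-to-H3 scale. Genes are sorted by id before clustering so labels
    do not depend on input order. ``minmax_scale`` optionally rescales each
    mark's block to [0, 1] before concatenation (off by default).
    """
    if not profile_sets:
        raise ValueError("need at least one profile set")
    index = profile_sets[0].index
    for ps in profile_sets[1:]:
        if not ps.index.equals(index):
            raise ValueError("all profile sets must share the same gene order")
    blocks = []
    for ps in profile_sets:
        block = ps.astype(float)
        if minmax_scale:
            lo, hi = np.nanmin(block.values), np.nanmax(block.values)
            if hi > lo:
                block = (block - lo) / (hi - lo)
        blocks.append(block)
    mat = pd.concat(blocks, axis=1)
    mat = mat.loc[sorted(mat.index)]
    keep = mat.isna().mean(axis=1) <= max_missing_frac
    mat = mat.loc[keep].fillna(0.0)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(mat):
        raise ValueError(f"k={k} exceeds the {len(mat)} usable genes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(mat.values)
    return ClusterResult(
        gene_ids=list(mat.index),
        assignments=labels + 1,
        centroids=km.cluster_centers_,
        within_cluster_ss=float(km.inertia_),
        k=k,
        seed=seed,
    )


def shannon_entropy(expression: Sequence[float]) -> float:
    """Shannon entropy (bits) of a gene's expression distribution over tissues.

    Values are normalized to a probability vector; zero entries drop out of
    the sum. Negative input raises; an all-zero vector yields NaN (entropy
    undefined for a silent gene).
    """
    x = np.asarray(expression, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def expression_summary(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean expression level across tissues and entropy in bits."""
    level = expr.mean(axis=1)
    entropy = expr.apply(lambda row: shannon_entropy(row.values), axis=1)
    return pd.DataFrame({"level": level, "entropy_bits": entropy})


def expression_group_summary(expr: pd.DataFrame, groups: Mapping[str, object]) -> pd.DataFrame:
    """25th/50th/75th percentiles of level and entropy per gene group.

    Percentiles use linear interpolation between order statistics.
    """
    summary = expression_summary(expr)
    assigned = pd.Series({gid: groups[gid] for gid in summary.index if gid in groups})
    rows = {}
    for label in sorted(set(assigned), key=str):
        members = summary.loc[assigned[assigned == label].index]
        if members.empty:
            raise ValueError(f"group {label!r} is empty")
        rows[label] = {
            "level_q25": float(np.percentile(members["level"], 25)),
            "level_q50": float(np.percentile(members["level"], 50)),
            "level_q75": float(np.percentile(members["level"], 75)),
            "entropy_q25": float(np.nanpercentile(members["entropy_bits"], 25)),
            "entropy_q50": float(np.nanpercentile(members["entropy_bits"], 50)),
            "entropy_q75": float(np.nanpercentile(members["entropy_bits"], 75)),
        }
    return pd.DataFrame(rows).T
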