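"""Enriched-region detection.

Per-probe moderated t-statistics are smoothed with a two-state
(background / enriched) hidden Markov model with Gaussian emissions;
probes whose posterior for the enriched state passes the cutoff are
merged under maximal-gap / minimal-run rules into enriched regions.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .types import EnrichedRegion, EnrichmentTrack, HMMConfig, ProbeTrack

__all__ = [
    "probe_t_statistics",
    "fit_two_state_hmm",
    "call_regions",
    "region_size_summary",
    "coverage_track",
]

_VAR_FLOOR = 1e-6


def probe_t_statistics(ip: ProbeTrack, input_: ProbeTrack, shrinkage: float = 0.5) -> EnrichmentTrack:
    """Moderated per-probe t-statistics comparing IP vs input replicates.

    t = (mean_IP - mean_input) / sqrt(s2 * (1/n_IP + 1/n_input)) where the
    variance estimate s2 shrinks each probe's pooled replicate variance
    toward the genome-wide median pooled variance with weight ``shrinkage``.
    Probes with a zero variance estimate get t = 0, keeping the track finite.
    """
    if ip.n_replicates < 2 or input_.n_replicates < 2:
        raise ValueError("t-statistics require at least two replicates per channel")
    if ip.chrom != input_.chrom or not np.array_equal(ip.positions, input_.positions):
        raise ValueError("IP and input tracks must cover identical probes")
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage weight must lie in [0, 1]")
    n_i, n_j = ip.n_replicates, input_.n_replicates
    ss_i = ((ip.values - ip.values.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_j = ((input_.values - input_.values.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled = (ss_i + ss_j) / (n_i + n_j - 2)
    s2 = shrinkage * np.median(pooled) + (1.0 - shrinkage) * pooled
    denom = np.sqrt(s2 * (1.0 / n_i + 1.0 / n_j))
    diff = ip.values.mean(axis=1) - input_.values.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return EnrichmentTrack(ip.chrom, ip.positions.copy(), t)


def _gauss_logpdf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def _forward_backward(b: np.ndarray, a00: float, a11: float, pi0: float, pi1: float):
    """Scaled forward-backward for a 2-state chain with fixed transitions.

    ``b`` is the (n, 2) emission likelihood matrix. Returns (log-likelihood,
    gamma) where gamma[:, k] is the posterior of state k per probe.
    """
    n = b.shape[0]
    a01, a10 = 1.0 - a00, 1.0 - a11
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    b0, b1 = b[:, 0], b[:, 1]

    f0 = pi0 * b0[0]
    f1 = pi1 * b1[0]
    c = f0 + f1
    if c <= 0.0:
        c = 1e-300
    alpha[0, 0], alpha[0, 1] = f0 / c, f1 / c
    scale[0] = c
    p0, p1 = alpha[0, 0], alpha[0, 1]
    for i in range(1, n):
        f0 = (p0 * a00 + p1 * a10) * b0[i]
        f1 = (p0 * a01 + p1 * a11) * b1[i]
        c = f0 + f1
        if c <= 0.0:
            c = 1e-300
        p0, p1 = f0 / c, f1 / c
        alpha[i, 0], alpha[i, 1] = p0, p1
        scale[i] = c

    beta = np.empty((n, 2))
    beta[n - 1, 0] = beta[n - 1, 1] = 1.0
    q0 = q1 = 1.0
    for i in range(n - 2, -1, -1):
        c = scale[i + 1]
        e0 = b0[i + 1] * q0
        e1 = b1[i + 1] * q1
        q0 = (a00 * e0 + a01 * e1) / c
        q1 = (a10 * e0 + a11 * e1) / c
        beta[i, 0], beta[i, 1] = q0, q1

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return float(np.log(scale).sum()), gamma


def fit_two_state_hmm(t_track: EnrichmentTrack, config: Optional[HMMConfig] = None) -> np.ndarray:
    """Posterior probability of the enriched state at every probe.

    Emissions are Gaussian; their means/variances are estimated by EM,
    initialized by splitting probes at the 90th percentile of t. Transition
    probabilities come from the config and are held fixed. A degenerate
    (constant) track returns an all-background posterior of zeros.
    """
    config = config or HMMConfig()
    t = np.asarray(t_track.value, dtype=float)
    n = t.size
    if n < 10:
        raise ValueError("HMM fitting requires at least 10 probes")
    if np.ptp(t) == 0.0:
        return np.zeros(n)

    thr = np.percentile(t, 90.0)
    low, high = t[t < thr], t[t >= thr]
    if low.size == 0 or high.size == 0:  # pathological but possible with heavy ties
        return np.zeros(n)
    mu = [float(low.mean()), float(high.mean())]
    var = [max(float(low.var()), _VAR_FLOOR), max(float(high.var()), _VAR_FLOOR)]

    a00 = config.stay_prob_background
    a11 = config.stay_prob_enriched
    # stationary distribution of the fixed transition matrix
    denom = (1.0 - a00) + (1.0 - a11)
    pi1 = (1.0 - a00) / denom
    pi0 = 1.0 - pi1

    prev_ll = -np.inf
    gamma = None
    for _ in range(config.em_max_iter):
        logb = np.column_stack([_gauss_logpdf(t, mu[0], var[0]), _gauss_logpdf(t, mu[1], var[1])])
        # per-row shift keeps the scaled recursion away from under/overflow
        shift = logb.max(axis=1, keepdims=True)
        b = np.exp(logb - shift)
        ll, gamma = _forward_backward(b, a00, a11, pi0, pi1)
        ll += float(shift.sum())
        for k in (0, 1):
            w = gamma[:, k]
            tot = w.sum()
            if tot <= 0:
                continue
            mu[k] = float((w * t).sum() / tot)
            var[k] = max(float((w * (t - mu[k]) ** 2).sum() / tot), _VAR_FLOOR)
        if abs(ll - prev_ll) < config.em_tol:
            break
        prev_ll = ll

    posterior = gamma[:, 1] if mu[1] >= mu[0] else gamma[:, 0]
    return np.clip(posterior, 0.0, 1.0)


def call_regions(
    posteriors: np.ndarray,
    positions: np.ndarray,
    config: Optional[HMMConfig] = None,
    chrom: str = "chr1",
    probe_spacing: Optional[int] = None,
) -> list[EnrichedRegion]:
    """Merge seed probes into enriched regions under gap/run/cutoff rules.

    Probes with posterior >= cutoff are seeds; consecutive seeds whose
    genomic gap is at most ``max_gap_bp`` merge into one region spanning
    first seed to last seed plus one probe spacing. Regions shorter than
    ``min_run_bp`` (measured on the merged span) are discarded.
    """
    config = config or HMMConfig()
    posteriors = np.asarray(posteriors, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if posteriors.shape != positions.shape:
        raise ValueError("posteriors and positions must have equal length")
    if positions.size > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be sorted strictly increasing")
    if probe_spacing is None:
        diffs = np.diff(positions)
        probe_spacing = int(diffs.min()) if diffs.size else 35

    seed_idx = np.flatnonzero(posteriors >= config.posterior_cutoff)
    regions: list[EnrichedRegion] = []
    if seed_idx.size == 0:
        return regions
    seed_pos = positions[seed_idx]
    breaks = np.flatnonzero(np.diff(seed_pos) > config.max_gap_bp)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [seed_idx.size - 1]])
    for s, e in zip(run_starts, run_ends):
        start = int(seed_pos[s])
        end = int(seed_pos[e]) + probe_spacing
        if end - start < config.min_run_bp:
            continue
        members = seed_idx[s : e + 1]
        regions.append(
            EnrichedRegion(
                chrom=chrom,
                start=start,
                end=end,
                mean_posterior=float(posteriors[members].mean()),
                n_probes=int(members.size),
            )
        )
    return regions


def region_size_summary(
    regions: Sequence[EnrichedRegion],
    hist_edges: Sequence[float] = (0, 200, 400, 600, 800, 1000, 2000, 4000, math.inf),
) -> dict:
    """Counts, >400 bp fraction, >1 kbp count, total extent and a length histogram."""
    lengths = np.array([r.length for r in regions], dtype=float)
    n = lengths.size
    edges = np.asarray(hist_edges, dtype=float)
    hist, _ = np.histogram(lengths, bins=edges) if n else (np.zeros(edges.size - 1, dtype=int), edges)
    return {
        "n_regions": int(n),
        "fraction_gt_400bp": float((lengths > 400).mean()) if n else 0.0,
        "n_gt_1kbp": int((lengths > 1000).sum()),
        "total_bp": int(lengths.sum()),
        "hist_edges": [float(e) for e in edges],
        "hist_counts": [int(c) for c in hist],
    }


def coverage_track(
    regions: Sequence[EnrichedRegion],
    chrom_lengths: dict[str, int],
    window_bp: int = 20_000,
) -> dict[str, np.ndarray]:
    """Percent of each non-overlapping ``window_bp`` window covered by regions.

    Regions straddling window boundaries contribute base-by-base to each
    window they intersect.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_win = max(1, math.ceil(length / window_bp))
        covered = np.zeros(n_win)
        # merge to a disjoint union so overlapping regions are not double-counted
        ivs = sorted((r.start, r.end) for r in regions if r.chrom == chrom)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            start, end = max(0, s), min(length, e)
            w = start // window_bp
            while w * window_bp < end:
                lo = max(start, w * window_bp)
                hi = min(end, (w + 1) * window_bp)
                if hi > lo:
                    covered[w] += hi - lo
                w += 1
        out[chrom] = 100.0 * covered / window_bp
    return out
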