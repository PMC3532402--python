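"""Probe-level signal normalization.

Raw linear-scale PM-MM values are floored and log2-transformed, replicate
columns are quantile-normalized, IP and input channels are scaled to a common
mean (an additive shift in log2 space), and the replicate-mean log ratio is
formed per probe. An optional per-probe subtraction of the total-H3 log ratio
yields the H3-adjusted enrichment track.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .types import EnrichmentTrack, ProbeTrack

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "scale_to_common_mean",
    "log_ratio",
    "h3_adjust",
    "normalize_channel_pair",
]


def log2_transform(track: ProbeTrack, floor: float = 1.0) -> ProbeTrack:
    """Return a track with every value replaced by ``log2(max(v, floor))``.

    Parameters
    ----------
    track
        Raw linear-scale PM-MM values (may contain non-positive entries).
    floor
        Positive lower clamp applied before the log; defaults to 1.0 so
        floored probes map to 0 on the log2 scale.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    vals = np.log2(np.maximum(track.values, floor))
    return ProbeTrack(track.chrom, track.positions.copy(), vals)


def quantile_normalize(columns: np.ndarray) -> np.ndarray:
    """Quantile-normalize >=2 equal-length columns.

    Every output column carries the same sorted values — the across-column
    mean of order statistics. Ties receive the mean of the tied
    order-statistic values (average-rank assignment), so the result is
    deterministic and permutation-invariant.
    """
    mat = np.asarray(columns, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D (probes x columns) array")
    if mat.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two columns")
    if mat.shape[0] < 1:
        raise ValueError("columns must be non-empty")
    reference = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        ranks = rankdata(mat[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(np.intp)
        hi = np.ceil(ranks).astype(np.intp)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return out


def scale_to_common_mean(ip: np.ndarray, input_: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shift both channels (log2 values) so their grand means coincide.

    The common target is the midpoint of the two original grand means;
    within-channel differences between probes are untouched.
    """
    ip = np.asarray(ip, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if ip.size == 0 or input_.size == 0:
        raise ValueError("cannot scale empty tracks")
    m_ip, m_in = ip.mean(), input_.mean()
    target = 0.5 * (m_ip + m_in)
    return ip + (target - m_ip), input_ + (target - m_in)


def log_ratio(ip: ProbeTrack, input_: ProbeTrack) -> EnrichmentTrack:
    """Per-probe replicate-mean log2(IP) minus replicate-mean log2(input)."""
    if ip.chrom != input_.chrom or not np.array_equal(ip.positions, input_.positions):
        raise ValueError("IP and input tracks must cover identical probes")
    value = ip.values.mean(axis=1) - input_.values.mean(axis=1)
    return EnrichmentTrack(ip.chrom, ip.positions.copy(), value)


def h3_adjust(mark: EnrichmentTrack, h3: EnrichmentTrack) -> EnrichmentTrack:
    """Subtract the total-H3 log ratio from a mark's log ratio, probe-wise."""
    if mark.chrom != h3.chrom or not np.array_equal(mark.positions, h3.positions):
        raise ValueError("mark and H3 tracks must cover identical probes")
    return EnrichmentTrack(mark.chrom, mark.positions.copy(), mark.value - h3.value)


def normalize_channel_pair(
    ip_raw: ProbeTrack, input_raw: ProbeTrack, floor: float = 1.0
) -> tuple[ProbeTrack, ProbeTrack, EnrichmentTrack]:
    """Full per-channel normalization chain for one mark.

    log2-transform each channel, quantile-normalize its replicate columns,
    scale IP and input to the common mean, and return the two normalized
    tracks plus their per-probe log ratio.
    """
    ip = log2_transform(ip_raw, floor)
    inp = log2_transform(input_raw, floor)
    if ip.n_replicates >= 2:
        ip.values = quantile_normalize(ip.values)
    if inp.n_replicates >= 2:
        inp.values = quantile_normalize(inp.values)
    ip.values, inp.values = scale_to_common_mean(ip.values, inp.values)
    return ip, inp, log_ratio(ip, inp)
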