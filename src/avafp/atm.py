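"""Avalanche transition matrices (ATMs).

For one avalanche, entry (i, j) estimates P(region j active at t + delta |
region i active at t), with t running over the avalanche's bins.  Per-subject
matrices are the element-wise mean over avalanches, then symmetrized as
(M + M^T)/2.  The lag (default one bin, 4 ms at 250 Hz) suppresses zero-lag
field-spread artefacts: simultaneous-only co-activations contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .avalanche import Avalanche

__all__ = ["TransitionMatrix", "avalanche_atm", "recording_atm", "vectorize_edges"]


@dataclass
class TransitionMatrix:
    """n_regions x n_regions lagged co-activation probabilities in [0, 1]."""

    values: np.ndarray
    roi_names: Sequence[str] | None
    delta_bins: int
    n_avalanches: int
    symmetric: bool
    n_short: int = 0  # avalanches too short to carry a lag-delta transition

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("TransitionMatrix.values must be square")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("TransitionMatrix entries must lie in [0, 1]")
        if self.symmetric and not np.array_equal(self.values, self.values.T):
            raise ValueError("symmetric flag set but matrix is not symmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def avalanche_atm(av: Avalanche, delta_bins: int = 1) -> TransitionMatrix:
    """Single-avalanche transition matrix (asymmetric).

    entry(i,j) = sum_t X(i,t) X(j,t+delta) / sum_t X(i,t), with t over bins
    0 .. Nbin-1-delta.  Rows whose region never fires in that window are
    zero-filled.  Avalanches with Nbin <= delta return the all-zero matrix,
    flagged through ``n_short``.
    """
    if delta_bins < 1:
        raise ValueError("delta_bins must be >= 1")
    if av.sub_raster is None:
        raise ValueError("avalanche carries no raster")
    X = av.sub_raster.astype(np.float64)
    n = X.shape[0]
    if av.n_bins <= delta_bins:
        return TransitionMatrix(
            values=np.zeros((n, n)),
            roi_names=None,
            delta_bins=delta_bins,
            n_avalanches=0,
            symmetric=False,
            n_short=1,
        )
    head, tail = X[:, :-delta_bins], X[:, delta_bins:]
    num = head @ tail.T
    denom = head.sum(axis=1)
    vals = np.divide(
        num, denom[:, None], out=np.zeros_like(num), where=denom[:, None] > 0
    )
    return TransitionMatrix(
        values=vals,
        roi_names=None,
        delta_bins=delta_bins,
        n_avalanches=1,
        symmetric=False,
    )


def recording_atm(
    avalanches: Sequence[Avalanche],
    delta_bins: int = 1,
    include_short: bool = False,
    roi_names: Sequence[str] | None = None,
) -> TransitionMatrix:
    """Per-recording ATM: mean of per-avalanche matrices, then symmetrized.

    Avalanches with Nbin <= delta_bins carry no lag-delta transition; by
    default they are excluded from the average (``include_short`` adds their
    all-zero matrices to the denominator).  Avalanches are batched by length
    so the average is a handful of einsums rather than a Python loop.
    """
    if len(avalanches) == 0:
        raise ValueError("recording_atm requires at least one avalanche")
    if delta_bins < 1:
        raise ValueError("delta_bins must be >= 1")
    if any(a.sub_raster is None for a in avalanches):
        raise ValueError("avalanche carries no raster")
    n = avalanches[0].sub_raster.shape[0]
    lens = np.array([a.n_bins for a in avalanches])
    long_idx = np.flatnonzero(lens > delta_bins)
    n_short = len(avalanches) - long_idx.size
    if long_idx.size == 0:
        if not include_short:
            raise ValueError(
                "recording_atm: every avalanche is shorter than the lag"
            )
        total, n_avg = np.zeros((n, n)), len(avalanches)
    else:
        total = np.zeros((n, n))
        for length in np.unique(lens[long_idx]):
            batch = [avalanches[i] for i in long_idx[lens[long_idx] == length]]
            X = np.stack([a.sub_raster for a in batch]).astype(np.float64)
            head, tail = X[:, :, :-delta_bins], X[:, :, delta_bins:]
            num = np.einsum("ait,ajt->aij", head, tail)
            denom = head.sum(axis=2)
            total += np.divide(
                num,
                denom[:, :, None],
                out=np.zeros_like(num),
                where=denom[:, :, None] > 0,
            ).sum(axis=0)
        n_avg = long_idx.size + (n_short if include_short else 0)
    mean = total / n_avg
    sym = (mean + mean.T) / 2.0
    return TransitionMatrix(
        values=sym,
        roi_names=list(roi_names) if roi_names is not None else None,
        delta_bins=delta_bins,
        n_avalanches=n_avg,
        symmetric=True,
        n_short=n_short,
    )


def vectorize_edges(atm: TransitionMatrix) -> np.ndarray:
    """Strict upper-triangle entries (i < j) in row-major ROI order.

    Length n(n-1)/2; the diagonal (self-transitions) is excluded.
    """
    if not atm.symmetric:
        raise ValueError("vectorize_edges requires a symmetric matrix")
    iu = np.triu_indices(atm.n_regions, k=1)
    return atm.values[iu]
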