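"""Edgewise test-retest stability via the intraclass correlation coefficient.

Within a group, each ATM edge yields an n_subjects x 2 (test/retest) table;
the one-way random-effects ICC(1,1) measures how consistently that edge ranks
subjects across sessions.  High ICC = a stable, stereotyped connection; a
flexible healthy brain shows low average edge stability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .atm import TransitionMatrix, vectorize_edges
from .stats import PermutationTestResult

__all__ = [
    "EdgeStability",
    "edge_icc",
    "node_stability",
    "group_mean_stability",
    "display_threshold",
    "stability_difference_test",
]


@dataclass
class EdgeStability:
    """Symmetric n_regions x n_regions ICC matrix; NaN marks undefined edges."""

    icc: np.ndarray
    group: str | None
    n_subjects: int
    variant: str = "icc1"

    def __post_init__(self) -> None:
        self.icc = np.asarray(self.icc, dtype=np.float64)
        if self.icc.ndim != 2 or self.icc.shape[0] != self.icc.shape[1]:
            raise ValueError("EdgeStability.icc must be square")
        if not np.array_equal(
            np.nan_to_num(self.icc, nan=-9.0), np.nan_to_num(self.icc.T, nan=-9.0)
        ):
            raise ValueError("EdgeStability.icc must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.icc.shape[0]


def _edge_table(
    test_atms: Sequence[TransitionMatrix],
    retest_atms: Sequence[TransitionMatrix],
) -> np.ndarray:
    """Stack to shape (n_subjects, 2, n_edges)."""
    if len(test_atms) != len(retest_atms):
        raise ValueError("mismatched subjects between sessions")
    T = np.stack([vectorize_edges(a) for a in test_atms])
    R = np.stack([vectorize_edges(a) for a in retest_atms])
    return np.stack([T, R], axis=1)


def _icc_from_table(X: np.ndarray, variant: str) -> np.ndarray:
    """Vectorized per-edge ICC from an (n, k, n_edges) table.

    icc1: one-way random effects, ICC(1,1) = (MSB - MSW)/(MSB + (k-1) MSW).
    icc2: two-way random effects, absolute agreement, single measure.
    icc3: two-way mixed effects, consistency, single measure.
    Edges with no variance at all (all mean squares zero) come back NaN.
    """
    n, k, _ = X.shape
    subj_mean = X.mean(axis=1)          # (n, e)
    sess_mean = X.mean(axis=0)          # (k, e)
    grand = X.mean(axis=(0, 1))         # (e,)
    msb = k * ((subj_mean - grand) ** 2).sum(axis=0) / (n - 1)
    ssw = ((X - subj_mean[:, None, :]) ** 2).sum(axis=(0, 1))
    msw = ssw / (n * (k - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "icc1":
            num, den = msb - msw, msb + (k - 1) * msw
        else:
            msc = n * ((sess_mean - grand) ** 2).sum(axis=0) / (k - 1)
            sse = ssw - (k - 1) * msc
            mse = sse / ((n - 1) * (k - 1))
            if variant == "icc3":
                num, den = msb - mse, msb + (k - 1) * mse
            elif variant == "icc2":
                num = msb - mse
                den = msb + (k - 1) * mse + k * (msc - mse) / n
            else:
                raise ValueError("variant must be icc1, icc2 or icc3")
        icc = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return icc


def edge_icc(
    test_atms: Sequence[TransitionMatrix],
    retest_atms: Sequence[TransitionMatrix],
    group: str | None = None,
    variant: str = "icc1",
) -> EdgeStability:
    """Per-edge test-retest ICC across the subjects of one group.

    Default is the one-way random-effects ICC(1,1) with k = 2 sessions;
    two-way variants are available as ``icc2``/``icc3``.
    """
    if len(test_atms) < 3:
        raise ValueError("edge_icc requires >= 3 subjects")
    X = _edge_table(test_atms, retest_atms)
    vals = _icc_from_table(X, variant)
    n_reg = test_atms[0].n_regions
    M = np.full((n_reg, n_reg), np.nan)
    iu = np.triu_indices(n_reg, k=1)
    M[iu] = vals
    M[(iu[1], iu[0])] = vals
    return EdgeStability(icc=M, group=group, n_subjects=len(test_atms), variant=variant)


def node_stability(es: EdgeStability) -> np.ndarray:
    """Per-region mean of defined incident-edge ICCs (NaN if none defined)."""
    M = es.icc.copy()
    np.fill_diagonal(M, np.nan)
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(M).sum(axis=1)
        sums = np.nansum(M, axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def group_mean_stability(es: EdgeStability) -> float:
    """Mean ICC over defined upper-triangle edges."""
    iu = np.triu_indices(es.n_regions, k=1)
    vals = es.icc[iu]
    return float(np.nanmean(vals))


def display_threshold(es: EdgeStability, cut: float = 0.65) -> EdgeStability:
    """Mask edges with ICC below ``cut`` (>= is retained), for display."""
    M = es.icc.copy()
    M[M < cut] = np.nan
    return replace(es, icc=M)


def stability_difference_test(
    test_a: Sequence[TransitionMatrix],
    retest_a: Sequence[TransitionMatrix],
    test_b: Sequence[TransitionMatrix],
    retest_b: Sequence[TransitionMatrix],
    n_perm: int = 10_000,
    seed: int | None = None,
    variant: str = "icc1",
) -> PermutationTestResult:
    """Permutation test on the group-mean edge ICC difference.

    ICC is a per-edge, group-level quantity, so group comparison is done by
    permuting subject labels between the two groups and recomputing the mean
    ICC of each relabeled group; the statistic is |mean ICC(a) - mean ICC(b)|.
    """
    Xa = _edge_table(test_a, retest_a)
    Xb = _edge_table(test_b, retest_b)
    na, nb = Xa.shape[0], Xb.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("each group needs >= 3 subjects")
    pooled = np.concatenate([Xa, Xb], axis=0)

    def mean_diff(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        ia = np.nanmean(_icc_from_table(pooled[idx_a], variant))
        ib = np.nanmean(_icc_from_table(pooled[idx_b], variant))
        return abs(ia - ib)

    obs = mean_diff(np.arange(na), np.arange(na, na + nb))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        if mean_diff(perm[:na], perm[na:]) >= obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(statistic=obs, p_perm=p, n_perm=n_perm, seed=seed)
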