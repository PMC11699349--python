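"""Identifiability ("neural fingerprint") indices from test/retest ATMs.

The identifiability matrix (IM) holds Pearson correlations between every
subject's test-session ATM edge vector (rows) and every subject's
retest-session edge vector (columns).  The diagonal gives the self-similarity
Iself; the off-diagonal entries involving a subject give Iothers; their
difference Idiff measures how identifiable the subject is within the group.
Iclinical correlates a patient's ATM with the average healthy-control ATM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atm import TransitionMatrix, vectorize_edges

__all__ = [
    "IdentifiabilityMatrix",
    "identifiability_matrix",
    "fingerprint_scores",
    "iclinical",
]


@dataclass
class IdentifiabilityMatrix:
    """Subjects x subjects Pearson matrix; rows = test, columns = retest."""

    values: np.ndarray
    subject_ids: Sequence[str]
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.subject_ids = list(self.subject_ids)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("IM shape must be (n_subjects, n_subjects)")
        if (np.abs(self.values) > 1 + 1e-12).any():
            raise ValueError("IM entries must lie in [-1, 1]")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _edge_matrix(atms: Sequence[TransitionMatrix]) -> np.ndarray:
    return np.stack([vectorize_edges(a) for a in atms])


def _standardize_rows(E: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Center and unit-normalize rows so that X @ Y.T gives Pearson r."""
    Ec = E - E.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Ec, axis=1)
    flat = np.flatnonzero(norms == 0)
    if flat.size:
        raise ValueError(f"zero-variance edge vector: {labels[flat[0]]}")
    return Ec / norms[:, None]


def identifiability_matrix(
    test_atms: Sequence[TransitionMatrix],
    retest_atms: Sequence[TransitionMatrix],
    subject_ids: Sequence[str] | None = None,
    group: str | None = None,
) -> IdentifiabilityMatrix:
    """Pearson r between each test edge vector and each retest edge vector."""
    if len(test_atms) != len(retest_atms):
        raise ValueError("test and retest ATM lists differ in length")
    if len(test_atms) < 2:
        raise ValueError("identifiability needs >= 2 subjects")
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(test_atms))]
    T = _standardize_rows(
        _edge_matrix(test_atms), [f"{s} (test)" for s in subject_ids]
    )
    R = _standardize_rows(
        _edge_matrix(retest_atms), [f"{s} (retest)" for s in subject_ids]
    )
    vals = np.clip(T @ R.T, -1.0, 1.0)
    return IdentifiabilityMatrix(values=vals, subject_ids=subject_ids, group=group)


def fingerprint_scores(
    im: IdentifiabilityMatrix, others: str = "both"
) -> pd.DataFrame:
    """Per-subject Iself, Iothers and Idiff from an identifiability matrix.

    Iself_i is the diagonal entry; Iothers_i averages the off-diagonal entries
    of row i and column i (``others='row'`` restricts to the row, i.e. the
    subject's test session against everyone else's retest); Idiff_i is their
    difference.  The frame's ``attrs`` carry the group label and mean Idiff.
    """
    if im.n_subjects < 2:
        raise ValueError("fingerprint scores need >= 2 subjects")
    if others not in ("both", "row"):
        raise ValueError("others must be 'both' or 'row'")
    V = im.values
    n = im.n_subjects
    iself = np.diag(V).copy()
    row_off = (V.sum(axis=1) - iself) / (n - 1)
    if others == "row":
        iothers = row_off
    else:
        col_off = (V.sum(axis=0) - iself) / (n - 1)
        iothers = (row_off + col_off) / 2.0
    df = pd.DataFrame(
        {"iself": iself, "iothers": iothers, "idiff": iself - iothers},
        index=pd.Index(im.subject_ids, name="subject_id"),
    )
    df.attrs["group"] = im.group
    df.attrs["group_idiff"] = float(df["idiff"].mean())
    return df


def _session_mean(pair: tuple[TransitionMatrix, TransitionMatrix]) -> np.ndarray:
    return (vectorize_edges(pair[0]) + vectorize_edges(pair[1])) / 2.0


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance edge vector in Iclinical")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def iclinical(
    patient_atms: dict[str, tuple[TransitionMatrix, TransitionMatrix]],
    control_atms: Sequence[tuple[TransitionMatrix, TransitionMatrix]],
    sessions: str = "both",
) -> pd.Series:
    """Similarity of each patient's ATM to the average healthy-control ATM.

    The reference edge vector is the mean over controls of each control's
    session-averaged ATM.  With ``sessions='both'`` (default) a patient's
    score averages the Pearson correlations of their test and retest edge
    vectors with the reference; 'test', 'retest' and 'average' use a single
    session or the patient's session-averaged ATM instead.
    """
    if len(control_atms) == 0:
        raise ValueError("Iclinical requires at least one control")
    if sessions not in ("both", "test", "retest", "average"):
        raise ValueError("sessions must be both/test/retest/average")
    reference = np.mean([_session_mean(p) for p in control_atms], axis=0)
    out = {}
    for sid, (test, retest) in patient_atms.items():
        if sessions == "both":
            out[sid] = (
                _pearson(vectorize_edges(test), reference)
                + _pearson(vectorize_edges(retest), reference)
            ) / 2.0
        elif sessions == "test":
            out[sid] = _pearson(vectorize_edges(test), reference)
        elif sessions == "retest":
            out[sid] = _pearson(vectorize_edges(retest), reference)
        else:
            out[sid] = _pearson(_session_mean((test, retest)), reference)
    s = pd.Series(out, name="iclinical")
    s.index.name = "subject_id"
    return s
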