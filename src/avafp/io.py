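"""Plain-text file formats: recordings, labeled square matrices, manifests.

Everything is delimited text for inspectability.  A recording file starts
with one header line of tab-separated ROI names followed by one numeric row
per ROI (columns = samples).  Square matrices (ATM, IM, edge ICC) are written
as labeled TSV with a JSON sidecar (<path>.meta.json) holding metadata such
as the lag, threshold, scale and group.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .avalanche import Recording
from .atm import TransitionMatrix
from .fingerprint import IdentifiabilityMatrix
from .stability import EdgeStability

log = logging.getLogger("avafp")

__all__ = [
    "read_recording",
    "write_recording",
    "write_matrix",
    "read_matrix",
    "write_manifest",
    "read_manifest",
]


def write_recording(path: str | Path, rec: Recording) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(rec.roi_names) + "\n")
        np.savetxt(fh, rec.data, fmt="%.6g", delimiter="\t")


def read_recording(
    path: str | Path,
    manifest_entry: Mapping[str, Any],
    n_regions: int = 68,
) -> Recording:
    """Parse a recording file and validate it against its manifest entry."""
    path = Path(path)
    with path.open() as fh:
        roi_names = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            try:
                row = np.array(cells, dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if not np.isfinite(row).all():
                col = int(np.flatnonzero(~np.isfinite(row))[0]) + 1
                raise ValueError(f"{path}:{lineno}: non-finite value in column {col}")
            rows.append(row)
    if len(rows) != n_regions:
        raise ValueError(f"{path}: expected {n_regions} ROIs, found {len(rows)}")
    expected = manifest_entry.get("roi_names")
    if expected is not None and list(expected) != roi_names:
        raise ValueError(f"{path}: ROI order differs from manifest")
    return Recording(
        subject_id=str(manifest_entry["subject_id"]),
        session=str(manifest_entry.get("session", "test")),
        group=str(manifest_entry["group"]),
        fs=float(manifest_entry.get("fs", 250.0)),
        roi_names=roi_names,
        data=np.vstack(rows),
    )


def _labels_and_values(obj) -> tuple[list[str], np.ndarray, dict[str, Any]]:
    if isinstance(obj, TransitionMatrix):
        labels = list(obj.roi_names) if obj.roi_names else [
            f"r{i}" for i in range(obj.n_regions)
        ]
        meta = {
            "kind": "atm",
            "delta_bins": obj.delta_bins,
            "n_avalanches": obj.n_avalanches,
            "symmetric": obj.symmetric,
            "n_short": obj.n_short,
        }
        return labels, obj.values, meta
    if isinstance(obj, IdentifiabilityMatrix):
        return list(obj.subject_ids), obj.values, {
            "kind": "im",
            "group": obj.group,
            "symmetric": False,
        }
    if isinstance(obj, EdgeStability):
        labels = [f"r{i}" for i in range(obj.n_regions)]
        return labels, obj.icc, {
            "kind": "icc",
            "group": obj.group,
            "n_subjects": obj.n_subjects,
            "variant": obj.variant,
            "symmetric": True,
        }
    raise TypeError(f"unsupported matrix object: {type(obj).__name__}")


def write_matrix(path: str | Path, obj, extra_meta: Mapping[str, Any] | None = None) -> None:
    """Write a labeled square matrix as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    labels, values, meta = _labels_and_values(obj)
    if meta.get("symmetric") and not np.array_equal(
        np.nan_to_num(values, nan=-9.0), np.nan_to_num(values.T, nan=-9.0)
    ):
        raise ValueError("matrix flagged symmetric is not symmetric")
    if extra_meta:
        meta.update(extra_meta)
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="label")
    Path(f"{path}.meta.json").write_text(json.dumps(meta, indent=1))


def read_matrix(
    path: str | Path, expect_labels: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str], dict[str, Any]]:
    """Read a labeled square matrix; returns (values, labels, metadata)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != labels:
        raise ValueError(f"{path}: row and column labels differ")
    if expect_labels is not None and list(expect_labels) != labels:
        raise ValueError(f"{path}: labels differ from expectation")
    sidecar = Path(f"{path}.meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        meta = {}
        warnings.warn(f"{path}: missing metadata sidecar; assuming defaults")
        log.warning("%s: missing metadata sidecar; assuming defaults", path)
    return df.to_numpy(dtype=np.float64), labels, meta


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(Path(path), sep="\t")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t").set_index("subject_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate subject_id in manifest: {dup}")
    bad = set(df["group"]) - {"HC", "UTLE-L", "UTLE-R", "BTLE"}
    if bad:
        raise ValueError(f"unknown group label(s) in manifest: {sorted(bad)}")
    return df
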