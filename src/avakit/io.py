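"""Readers and writers for series, manifests, matrices, and reports.

On-disk layout:

* a subject's series is a TSV/CSV with one row per ROI and one column per
  sample, accompanied by a YAML sidecar (same stem, ``.yaml``) carrying
  ``fs``, ``roi_labels``, ``segment_bounds``, ``subject_id`` and ``group``;
* a cohort manifest is a TSV with columns ``subject_id``, ``group``,
  ``path`` (series path relative to the manifest's directory);
* connectivity/transition matrices are TSV with ROI labels as header row
  and first column, preceded by ``#``-prefixed metadata lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .avalanches import TransitionMatrix
from .connectivity import ConnectivityMatrix
from .containers import RoiTimeSeries

__all__ = [
    "write_series",
    "read_series",
    "write_manifest",
    "read_manifest",
    "write_matrix",
    "read_matrix",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_series(ts: RoiTimeSeries, path: str | Path, fmt: str = "%.6g") -> Path:
    """Write a series as delimited text plus its YAML sidecar."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    np.savetxt(path, ts.data, fmt=fmt, delimiter=sep)
    meta = {
        "fs": float(ts.fs),
        "roi_labels": list(ts.roi_labels),
        "segment_bounds": [[int(a), int(b)] for a, b in ts.segment_bounds],
        "subject_id": ts.subject_id,
        "group": ts.group,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_series(path: str | Path) -> RoiTimeSeries:
    """Read a series TSV/CSV and its YAML sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata: {sidecar}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    data = np.loadtxt(path, delimiter=sep, ndmin=2)
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    return RoiTimeSeries(
        data=data,
        fs=float(meta["fs"]),
        roi_labels=[str(x) for x in meta["roi_labels"]],
        segment_bounds=[tuple(b) for b in meta.get("segment_bounds") or []] or None,
        subject_id=str(meta.get("subject_id", path.stem)),
        group=meta.get("group"),
    )


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a manifest TSV with columns subject_id, group, path."""
    path = Path(path)
    pd.DataFrame(rows, columns=["subject_id", "group", "path"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest TSV; relative series paths resolve against it."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    df["path"] = [
        str((path.parent / p) if not Path(p).is_absolute() else p) for p in df["path"]
    ]
    return df


def write_matrix(
    mat: TransitionMatrix | ConnectivityMatrix,
    path: str | Path,
    extra_meta: dict | None = None,
) -> Path:
    """Write a labeled matrix as TSV with '#'-prefixed metadata lines."""
    path = Path(path)
    if isinstance(mat, TransitionMatrix):
        values = mat.probs
        meta = {
            "kind": "atm",
            "delta_bins": mat.delta_bins,
            "n_avalanches": mat.n_avalanches_averaged,
        }
    else:
        values = mat.values
        meta = {"kind": mat.kind, "band": f"{mat.band[0]:g}-{mat.band[1]:g}Hz"}
    meta.update(extra_meta or {})
    labels = mat.roi_labels or [f"roi{r:03d}" for r in range(values.shape[0])]
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("roi\t" + "\t".join(labels) + "\n")
        for r, lab in enumerate(labels):
            fh.write(lab + "\t" + "\t".join(f"{x:.8g}" for x in values[r]) + "\n")
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], dict]:
    """Read a labeled matrix TSV; returns (values, roi_labels, metadata)."""
    path = Path(path)
    meta: dict = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line:
                rows.append(line.split("\t"))
    header = rows[0][1:]
    labels = [r[0] for r in rows[1:]]
    if labels != header:
        raise ValueError(f"matrix {path}: row labels do not match header")
    values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return values, labels, meta
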