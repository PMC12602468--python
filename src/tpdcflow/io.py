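"""Readers and writers for time-series tables, connectivity matrices, reports.

All tabular files are TSV. Matrix files carry comment header lines stating
the matrix kind and the orientation convention (entry (i,j) = influence of
column j on row i). Floats are serialized with 17 significant digits so a
write/load round trip is lossless; writers are deterministic (same record
-> byte-identical file, '\n' line endings).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MATRIX_KINDS, MatrixRecord, TimeSeriesSet

_FLOAT_FMT = "%.17g"
_CONVENTION = "rows=target i, columns=source j; entry (i,j) = influence j->i"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def load_timeseries(
    path: str | Path,
    tr: float,
    subject_id: str | None = None,
    group: str | None = None,
) -> TimeSeriesSet:
    """Load a T x N delimited table (header row of channel names) as a subject.

    TR is supplied by the caller: plain tables carry no time metadata.
    Validation errors name the offending row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header:
        raise ValueError(f"{path}: empty file or missing header")
    channels = header.split("\t")
    try:
        [float(c) for c in channels]
    except ValueError:
        pass  # non-numeric header: good
    else:
        raise ValueError(f"{path}: first row is numeric; expected a header of channel names")

    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    data = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i}, column {col!r}"
                ) from None
            if not np.isfinite(val):
                raise ValueError(
                    f"{path}: non-finite value at row {i}, column {col!r}"
                )
            data[i, j] = val
    return TimeSeriesSet(
        subject_id=subject_id if subject_id is not None else path.stem,
        data=data,
        channels=tuple(frame.columns),
        tr=tr,
        group=group,
    )


def save_timeseries(ts: TimeSeriesSet, path: str | Path) -> Path:
    """Write a subject's series as TSV: header of channel names, one row per sample."""
    path = Path(path)
    lines = ["\t".join(ts.channels)]
    for row in ts.data:
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def save_matrix(rec: MatrixRecord, path: str | Path) -> Path:
    """Write a labelled N x N matrix as TSV with kind/convention comment header."""
    path = Path(path)
    lines = [
        f"# kind: {rec.kind}",
        f"# convention: {_CONVENTION}",
        f"# subject: {rec.subject_id}",
        "\t".join(("",) + rec.channels),
    ]
    for name, row in zip(rec.channels, rec.values):
        lines.append(name + "\t" + "\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def load_matrix(path: str | Path) -> MatrixRecord:
    """Load a matrix written by :func:`save_matrix`, validating kind and labels."""
    path = Path(path)
    kind = None
    subject = ""
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("# kind:"):
            kind = line.split(":", 1)[1].strip()
        elif line.startswith("# subject:"):
            subject = line.split(":", 1)[1].strip()
        elif line.startswith("#"):
            continue
        elif line.strip():
            body.append(line)
    if kind is None or kind not in MATRIX_KINDS:
        raise ValueError(f"{path}: missing or unknown '# kind:' header ({kind!r})")
    if not body:
        raise ValueError(f"{path}: no matrix body")
    col_names = body[0].split("\t")[1:]
    rows = []
    row_names = []
    for line in body[1:]:
        parts = line.split("\t")
        row_names.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if row_names != col_names:
        raise ValueError(f"{path}: row labels {row_names} != column labels {col_names}")
    values = np.asarray(rows, dtype=float)
    if values.shape != (len(col_names), len(col_names)):
        raise ValueError(f"{path}: non-square body {values.shape}")
    return MatrixRecord(
        subject_id=subject, values=values, kind=kind, channels=tuple(col_names)
    )


def save_report(report: dict, path: str | Path) -> Path:
    """Write an analysis report (metrics, correlations, thresholds) as JSON."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return path


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
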