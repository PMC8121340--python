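"""File formats: boundary-trace CSV, 8-bit grayscale images, YAML configs.

Traces travel in one dialect everywhere: a CSV with header
``scan_id,edge,column,row`` where edge is ILM/RPE/BM, column is 0-based and
row is a fractional pixel position (empty row field = missing column).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .boundary import BoundaryTrace

VALID_EDGES = {"ILM", "RPE", "BM"}

TraceDict = dict[str, dict[str, "np.ndarray | BoundaryTrace"]]


class TraceFormatError(ValueError):
    pass


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG or TIFF (by extension)."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), img)


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img, dtype=np.uint8)


def _rows_of(trace) -> np.ndarray:
    return trace.rows if isinstance(trace, BoundaryTrace) else np.asarray(trace, float)


def write_traces(traces: TraceDict, path: str | Path) -> None:
    """Write {scan_id -> {edge -> trace}} in the shared CSV dialect."""
    records = []
    for sid in sorted(traces):
        for edge in sorted(traces[sid]):
            if edge.upper() not in VALID_EDGES:
                raise TraceFormatError(f"unknown edge name {edge!r} for scan {sid!r}")
            rows = _rows_of(traces[sid][edge])
            for col, r in enumerate(rows):
                records.append((sid, edge.upper(), col, "" if np.isnan(r) else f"{r:.6f}"))
    df = pd.DataFrame(records, columns=["scan_id", "edge", "column", "row"])
    df.to_csv(path, index=False)


def read_traces(path: str | Path) -> dict[str, dict[str, BoundaryTrace]]:
    """Read the trace CSV; out-of-order columns are accepted and sorted.

    Malformed rows raise :class:`TraceFormatError` with the 1-based line
    number (header = line 1).
    """
    try:
        df = pd.read_csv(path, dtype={"scan_id": str, "edge": str},
                         keep_default_na=False)
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise TraceFormatError(f"cannot parse {path}: {e}") from e
    required = ["scan_id", "edge", "column", "row"]
    if list(df.columns) != required:
        raise TraceFormatError(f"{path}: expected header {required}, got {list(df.columns)}")

    def fail(i: int, msg: str):
        raise TraceFormatError(f"{path}, line {i + 2}: {msg}")

    out: dict[str, dict[str, dict[int, float]]] = {}
    for i, rec in enumerate(df.itertuples(index=False)):
        edge = str(rec.edge).upper()
        if edge not in VALID_EDGES:
            fail(i, f"unknown edge name {rec.edge!r}")
        try:
            col = int(rec.column)
        except (TypeError, ValueError):
            fail(i, f"bad column index {rec.column!r}")
        if col < 0:
            fail(i, f"negative column index {col}")
        row_str = str(rec.row).strip()
        if row_str in ("", "nan", "NaN"):
            row = np.nan
        else:
            try:
                row = float(row_str)
            except ValueError:
                fail(i, f"bad row value {rec.row!r}")
        out.setdefault(str(rec.scan_id), {}).setdefault(edge, {})[col] = row

    result: dict[str, dict[str, BoundaryTrace]] = {}
    for sid, edges in out.items():
        result[sid] = {}
        for edge, colmap in edges.items():
            width = max(colmap) + 1
            rows = np.full(width, np.nan)
            for c, r in colmap.items():
                rows[c] = r
            result[sid][edge] = BoundaryTrace(rows=rows)
    return result


def save_config(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
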