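"""Trace bookkeeping between pipeline stages.

Converts coarse label maps into per-edge band crops, fused edge maps into
single-valued per-column boundary traces, and traces between crop/network
coordinates and original B-scan coordinates.  Boundary positions are kept at
sub-pixel (float) precision; columns without a detection are NaN and tracked
by the ``missing`` property.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: coarse classes per edge group
GROUP_CLASSES = {"ILM": (1,), "RPE/BM": (2, 3)}


class TraceError(RuntimeError):
    """No usable boundary could be extracted."""


@dataclass(frozen=True)
class CropGeometry:
    """Placement of a (possibly resized) crop inside the original B-scan.

    ``row_scale``/``col_scale`` map crop pixels to network-input pixels
    (network = crop * scale); offsets are the crop origin in the original
    image.
    """

    row_offset: int
    col_offset: int
    row_scale: float = 1.0
    col_scale: float = 1.0

    def __post_init__(self):
        if self.row_scale <= 0 or self.col_scale <= 0:
            raise ValueError(f"scales must be > 0, got {self.row_scale}, {self.col_scale}")

    def compose(self, outer: "CropGeometry") -> "CropGeometry":
        """Geometry of this crop nested inside ``outer`` (outer has unit scale)."""
        return CropGeometry(
            row_offset=outer.row_offset + self.row_offset,
            col_offset=outer.col_offset + self.col_offset,
            row_scale=self.row_scale,
            col_scale=self.col_scale,
        )


@dataclass
class BoundaryTrace:
    """Per-column fractional row positions; NaN marks missing columns."""

    rows: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.float64)

    @property
    def width(self) -> int:
        return len(self.rows)

    @property
    def missing(self) -> set[int]:
        return set(np.flatnonzero(np.isnan(self.rows)).tolist())

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rows)


def coarse_to_crop(img: np.ndarray, labels: np.ndarray, edge_group: str,
                   margin: int = 10) -> tuple[np.ndarray, CropGeometry]:
    """Crop the bounding box of a coarse class band, expanded by ``margin``.

    ``edge_group`` is ``"ILM"`` or ``"RPE/BM"``.  If the requested class is
    absent from the label map, the full image is returned (with a logged
    warning) so the pipeline degrades to the ROI crop instead of failing.
    """
    if edge_group not in GROUP_CLASSES:
        raise ValueError(f"edge_group must be one of {sorted(GROUP_CLASSES)}, "
                         f"got {edge_group!r}")
    labels = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    if labels.shape != img.shape:
        raise ValueError(f"label map shape {labels.shape} != image {img.shape}")
    sel = np.isin(labels, GROUP_CLASSES[edge_group])
    if not sel.any():
        log.warning("coarse_to_crop: class group %s absent from label map; "
                    "falling back to the full crop", edge_group)
        return img, CropGeometry(0, 0)
    rows = np.flatnonzero(sel.any(axis=1))
    cols = np.flatnonzero(sel.any(axis=0))
    r0 = max(0, int(rows[0]) - margin)
    r1 = min(img.shape[0], int(rows[-1]) + 1 + margin)
    c0 = max(0, int(cols[0]) - margin)
    c1 = min(img.shape[1], int(cols[-1]) + 1 + margin)
    return img[r0:r1, c0:c1], CropGeometry(row_offset=r0, col_offset=c0)


def edge_map_to_trace(em, threshold_frac: float = 0.3) -> BoundaryTrace:
    """Reduce a fused edge-probability map to one sub-pixel row per column.

    Per column: with m the column maximum, columns where m falls below
    ``threshold_frac`` of the global maximum are marked missing; otherwise
    the trace row is the probability-weighted centroid of the rows where
    p >= 0.5 * m.  Missing columns are then filled by linear interpolation
    between the nearest defined neighbors (nearest-neighbor extension at the
    ends).
    """
    fused = np.asarray(em.fused if hasattr(em, "fused") else em, dtype=np.float64)
    gmax = fused.max()
    if gmax <= 0:
        raise TraceError("edge map is identically zero: no detection")
    h, w = fused.shape
    rows_idx = np.arange(h)
    out = np.full(w, np.nan)
    col_max = fused.max(axis=0)
    for c in range(w):
        m = col_max[c]
        if m < threshold_frac * gmax:
            continue
        sel = fused[:, c] >= 0.5 * m
        p = fused[sel, c]
        out[c] = float((rows_idx[sel] * p).sum() / p.sum())
    defined = ~np.isnan(out)
    if not defined.any():
        raise TraceError("no column passed the detection threshold")
    if not defined.all():
        xs = np.flatnonzero(defined)
        out = np.interp(np.arange(w), xs, out[xs])  # interp extends ends as NN
    return BoundaryTrace(rows=out)


def map_trace_to_original(trace: BoundaryTrace, geom: CropGeometry,
                          out_width: int, image_height: int | None = None) -> BoundaryTrace:
    """Map a trace from network coordinates back to original B-scan columns.

    Network row r lies at original row r / row_scale + row_offset; network
    column j at original column j / col_scale + col_offset.  The result is
    resampled at integer original columns; columns outside the crop's lateral
    footprint are missing.  Rows landing outside ``image_height`` are clipped
    with a warning.
    """
    rows = trace.rows
    ncols = len(rows)
    defined = ~np.isnan(rows)
    if not defined.any():
        raise TraceError("cannot map an all-missing trace")
    orig_cols_of_net = np.arange(ncols) / geom.col_scale + geom.col_offset
    orig_rows_of_net = rows / geom.row_scale + geom.row_offset
    out = np.full(out_width, np.nan)
    lo = int(np.ceil(orig_cols_of_net[defined].min()))
    hi = int(np.floor(orig_cols_of_net[defined].max()))
    lo, hi = max(lo, 0), min(hi, out_width - 1)
    if lo > hi:
        raise TraceError("crop footprint does not overlap the output columns")
    cc = np.arange(lo, hi + 1)
    out[cc] = np.interp(cc, orig_cols_of_net[defined], orig_rows_of_net[defined])
    if image_height is not None:
        bad = (out < 0) | (out > image_height - 1)
        bad &= ~np.isnan(out)
        if bad.any():
            warnings.warn(f"map_trace_to_original: {int(bad.sum())} columns mapped "
                          "outside the image and were clipped", stacklevel=2)
            out = np.clip(out, 0, image_height - 1)
    return BoundaryTrace(rows=out)


def fill_trace_ends(trace: BoundaryTrace) -> BoundaryTrace:
    """Extend a trace to every column (linear interior, nearest at the ends)."""
    rows = trace.rows.copy()
    defined = ~np.isnan(rows)
    if not defined.any():
        raise TraceError("cannot fill an all-missing trace")
    xs = np.flatnonzero(defined)
    rows = np.interp(np.arange(len(rows)), xs, rows[xs])
    return BoundaryTrace(rows=rows)
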