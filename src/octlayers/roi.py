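"""Region-of-interest extraction: find the retina band inside a B-scan.

The retina occupies a bright horizontal band in an otherwise dark scan, so a
global Otsu threshold followed by morphological cleanup delimits it cheaply:

1. binarize at the Otsu threshold (foreground = pixels strictly above it);
2. morphological opening, 5x5 square element, 2 iterations (drops speckle
   survivors);
3. morphological dilation, 5x5 square element, 7 iterations (closes the band
   and adds a safety margin);
4. remove connected components smaller than 1000 px (8-connectivity).

The surviving mask's tight bounding box is the ROI; downstream networks see
the rectangular crop, not a masked image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

STRUCT_5X5 = np.ones((5, 5), dtype=bool)


class ROIError(RuntimeError):
    """No retina region could be delimited in a scan."""


@dataclass(frozen=True)
class ROIParams:
    opening_iterations: int = 2
    dilation_iterations: int = 7
    min_area: int = 1000


@dataclass
class ROIMask:
    """Binary retina mask plus its tight bounding box (half-open, 0-based)."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def otsu_threshold(img: np.ndarray) -> int:
    """Integer Otsu threshold on the 0..255 histogram; foreground is > t.

    A constant image has no meaningful split: the constant itself is returned
    with a warning (the downstream mask is then empty and define_roi raises).
    """
    img = np.asarray(img)
    if img.min() == img.max():
        warnings.warn(
            f"otsu_threshold: constant image (value {int(img.min())}), threshold degenerate",
            stacklevel=2,
        )
        return int(img.min())
    t = threshold_otsu(img.astype(np.uint8), nbins=256)
    return int(t)


def define_roi(img: np.ndarray, params: ROIParams | None = None, scan_id: str = "?") -> ROIMask:
    """Run the full Otsu → opening → dilation → area-filter pipeline."""
    params = params or ROIParams()
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D B-scan, got shape {img.shape}")

    t = otsu_threshold(img)
    binary = img > t
    opened = apply_opening(binary, params.opening_iterations)
    dilated = apply_dilation(opened, params.dilation_iterations)
    mask = filter_small_components(dilated, params.min_area)
    if not mask.any():
        raise ROIError(f"no retina region found in scan {scan_id!r} "
                       f"(empty mask after morphology/area filter)")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return ROIMask(mask=mask, bbox=bbox)


def apply_opening(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Morphological opening with the 5x5 square element."""
    return ndimage.binary_opening(np.asarray(mask, dtype=bool),
                                  structure=STRUCT_5X5, iterations=iterations)


def apply_dilation(mask: np.ndarray, iterations: int = 7) -> np.ndarray:
    """Morphological dilation with the 5x5 square element."""
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool),
                                   structure=STRUCT_5X5, iterations=iterations)


def filter_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with area < min_area (keeps area >= min_area)."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def crop_to_roi(img: np.ndarray, roi: ROIMask) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop to the ROI bounding box; returns (crop, (row_offset, col_offset))."""
    if not roi.mask.any():
        raise ROIError("cannot crop to an empty ROI")
    r0, r1, c0, c1 = roi.bbox
    return img[r0:r1, c0:c1], (r0, c0)
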