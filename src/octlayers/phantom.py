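"""Synthetic layered-retina phantoms with known boundary traces.

Each phantom is a 2-D grayscale B-scan (rows = depth, y increasing downward;
columns = lateral A-scan positions) built from three sub-pixel boundary
curves:

* **ILM** — a smooth upper curve with an inverted-Gaussian foveal dip,
* **BM**  — a smooth lower curve (Bruch's membrane stays smooth even under
  pathology),
* **RPE** — the BM curve minus a baseline offset and minus a sum of Gaussian
  drusen bumps, so drusen lift the RPE *upward* while BM is undisturbed.

Intensity bands (vitreous / ILM band / inner retina / RPE band / sub-BM) are
painted between the rounded curves and multiplicative Gamma speckle is
applied last.  The traces are returned at float precision and are the ground
truth for every downstream stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

EDGES = ("ILM", "RPE", "BM")

#: painted thickness of the bright ILM band, in pixels
ILM_BAND_THICKNESS = 3


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its geometric bounds."""


@dataclass(frozen=True)
class Druse:
    """One forced druse: a Gaussian bump lifting RPE above BM."""

    column: float
    amplitude: float  # px lift at the apex
    width: float      # lateral std of the Gaussian, px


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of a synthetic B-scan.

    Depth positions are rows (pixels, y downward).  ``drusen_amp_range`` and
    ``drusen_width_range`` are inclusive (min, max) bounds for the uniform
    draws used per druse; ``forced_drusen`` adds deterministic drusen on top
    of the Poisson-sampled ones (useful for targeted tests).
    """

    width: int = 1000
    height: int = 512
    ilm_depth: float = 120.0
    rpe_depth: float = 320.0
    bm_offset: float = 6.0
    fovea_amplitude: float = 30.0
    drusen_count_mean: float = 3.0
    drusen_amp_range: tuple[float, float] = (8.0, 30.0)
    drusen_width_range: tuple[float, float] = (15.0, 60.0)
    band_intensities: tuple[int, int, int, int, int] = (20, 190, 90, 210, 45)
    speckle_level: float = 0.25
    forced_drusen: tuple[Druse, ...] = ()

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise PhantomSpecError(f"image size {self.height}x{self.width} too small")
        if not (0 < self.ilm_depth < self.rpe_depth < self.height):
            raise PhantomSpecError(
                "need 0 < ilm_depth < rpe_depth < height, got "
                f"ilm_depth={self.ilm_depth}, rpe_depth={self.rpe_depth}, "
                f"height={self.height}"
            )
        if self.bm_offset < 0:
            raise PhantomSpecError(f"bm_offset must be >= 0, got {self.bm_offset}")
        for name, rng in (
            ("drusen_amp_range", self.drusen_amp_range),
            ("drusen_width_range", self.drusen_width_range),
        ):
            lo, hi = rng
            if not (0 < lo <= hi):
                raise PhantomSpecError(f"{name} must be positive and ordered, got {rng}")
        max_amp = self.drusen_amp_range[1]
        if self.forced_drusen:
            max_amp = max(max_amp, max(d.amplitude for d in self.forced_drusen))
        if self.rpe_depth + self.bm_offset + 4.0 >= self.height:
            raise PhantomSpecError(
                f"rpe_depth + bm_offset = {self.rpe_depth + self.bm_offset} leaves no room "
                f"below BM in height {self.height}"
            )
        # drusen lift RPE upward; the dipped ILM must stay above the lifted RPE
        if self.ilm_depth + self.fovea_amplitude >= self.rpe_depth - max_amp:
            raise PhantomSpecError(
                "ILM foveal dip may cross the drusen-lifted RPE: require "
                f"ilm_depth + fovea_amplitude ({self.ilm_depth + self.fovea_amplitude}) "
                f"< rpe_depth - max drusen amplitude ({self.rpe_depth - max_amp})"
            )
        if self.speckle_level < 0:
            raise PhantomSpecError(f"speckle_level must be >= 0, got {self.speckle_level}")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)

    @classmethod
    def scaled(cls, width: int = 1000, height: int = 512,
               drusen_count_mean: float = 3.0,
               speckle_level: float = 0.25, **kw) -> "PhantomSpec":
        """Spec with depth geometry scaled proportionally to the image size.

        The default 512 x 1000 geometry shrinks consistently to small test
        sizes (e.g. 128 x 256) while keeping all validity bounds satisfied.
        """
        s = height / 512
        defaults = dict(
            width=width, height=height,
            ilm_depth=120 * s, rpe_depth=320 * s, bm_offset=max(2.0, 6 * s),
            fovea_amplitude=30 * s,
            drusen_count_mean=drusen_count_mean,
            drusen_amp_range=(8 * s, 30 * s),
            drusen_width_range=(max(4.0, 0.015 * width), max(8.0, 0.06 * width)),
            speckle_level=speckle_level,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class GroundTruthSet:
    """Per-column row positions of the three boundaries (fractional pixels)."""

    ilm: np.ndarray
    rpe: np.ndarray
    bm: np.ndarray

    def trace(self, edge: str) -> np.ndarray:
        return {"ILM": self.ilm, "RPE": self.rpe, "BM": self.bm}[edge.upper()]

    def ordering_ok(self) -> np.ndarray:
        """Boolean per column: ILM < RPE <= BM (y downward)."""
        return (self.ilm < self.rpe) & (self.rpe <= self.bm + 1e-9)


def _smooth_curve(rng: np.random.Generator, width: int, mean: float,
                  tilt_px: float, bend_px: float) -> np.ndarray:
    """Gentle low-order curve: mean + random tilt + random quadratic bend."""
    x = np.linspace(-1.0, 1.0, width)
    tilt = rng.uniform(-tilt_px, tilt_px)
    bend = rng.uniform(-bend_px, bend_px)
    return mean + tilt * x + bend * (x ** 2)


def _sample_drusen(rng: np.random.Generator, spec: PhantomSpec) -> list[Druse]:
    n = rng.poisson(spec.drusen_count_mean) if spec.drusen_count_mean > 0 else 0
    out = []
    for _ in range(n):
        col = rng.uniform(0.05 * spec.width, 0.95 * spec.width)
        amp = rng.uniform(*spec.drusen_amp_range)
        wid = rng.uniform(*spec.drusen_width_range)
        out.append(Druse(col, amp, wid))
    return out + list(spec.forced_drusen)


def generate_bscan(
    spec: PhantomSpec, seed: int, return_drusen: bool = False
) -> tuple[np.ndarray, GroundTruthSet] | tuple[np.ndarray, GroundTruthSet, list[Druse]]:
    """Generate one synthetic B-scan and its ground-truth traces.

    Deterministic in (spec, seed).  Returns an (height, width) uint8 image and
    a :class:`GroundTruthSet` defined on every column; with
    ``return_drusen=True`` also the list of injected drusen.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    w, h = spec.width, spec.height
    cols = np.arange(w, dtype=np.float64)

    # ILM: smooth base + inverted-Gaussian foveal dip (dip goes downward)
    ilm = _smooth_curve(rng, w, spec.ilm_depth, tilt_px=0.02 * h, bend_px=0.02 * h)
    fovea_center = rng.uniform(0.35 * w, 0.65 * w)
    fovea_sigma = rng.uniform(0.06 * w, 0.12 * w)
    ilm = ilm + spec.fovea_amplitude * np.exp(-0.5 * ((cols - fovea_center) / fovea_sigma) ** 2)

    # BM: smooth, stays smooth regardless of drusen
    bm = _smooth_curve(rng, w, spec.rpe_depth + spec.bm_offset,
                       tilt_px=0.02 * h, bend_px=0.03 * h)

    drusen = _sample_drusen(rng, spec)
    lift = np.zeros(w)
    for d in drusen:
        lift += d.amplitude * np.exp(-0.5 * ((cols - d.column) / d.width) ** 2)
    rpe = bm - spec.bm_offset - lift

    img = _paint(spec, ilm, rpe, bm)
    if spec.speckle_level > 0:
        k = 1.0 / (spec.speckle_level ** 2)
        noise = rng.gamma(shape=k, scale=1.0 / k, size=img.shape)
        img = np.clip(img.astype(np.float64) * noise, 0, 255)
    img = np.round(img).astype(np.uint8)

    gt = GroundTruthSet(ilm=ilm, rpe=rpe, bm=bm)
    if return_drusen:
        return img, gt, drusen
    return img, gt


def _paint(spec: PhantomSpec, ilm: np.ndarray, rpe: np.ndarray, bm: np.ndarray) -> np.ndarray:
    """Paint intensity bands between the rounded traces."""
    vit, ilm_band, inner, rpe_band, below = spec.band_intensities
    h, w = spec.height, spec.width
    rows = np.arange(h)[:, None]
    ilm_r = np.round(ilm)[None, :]
    rpe_r = np.round(rpe)[None, :]
    bm_r = np.round(bm)[None, :]
    img = np.full((h, w), float(vit))
    img[(rows >= ilm_r) & (rows < ilm_r + ILM_BAND_THICKNESS)] = ilm_band
    img[(rows >= ilm_r + ILM_BAND_THICKNESS) & (rows < rpe_r)] = inner
    img[(rows >= rpe_r) & (rows <= bm_r)] = rpe_band
    img[rows > bm_r] = below
    return img


def generate_dataset(
    spec: PhantomSpec,
    n: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[tuple[np.ndarray, GroundTruthSet]]:
    """Generate ``n`` independent phantoms seeded ``seed + i``.

    When ``out_dir`` is given, images are written as 8-bit grayscale PNGs
    (``scan_000.png`` ...) and all traces to one ``traces.csv`` in the shared
    ``scan_id,edge,column,row`` dialect.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 scans, got {n}")
    scans = [generate_bscan(spec, seed + i) for i in range(n)]
    if out_dir is not None:
        from . import io as _io  # local import: io pulls pandas/imageio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traces = {}
        for i, (img, gt) in enumerate(scans):
            scan_id = f"scan_{i:03d}"
            _io.write_image(img, out / f"{scan_id}.png")
            traces[scan_id] = {e: gt.trace(e) for e in EDGES}
        _io.write_traces(traces, out / "traces.csv")
    return scans
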