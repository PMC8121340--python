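"""End-to-end four-stage pipeline: denoise → ROI → coarse bands → per-edge
fine segmentation → boundary traces, plus the training driver that fits the
coarse model and the three per-edge models on phantoms (or any dataset of
B-scans with ground-truth traces).

Coordinate bookkeeping: ROI crops have unit scale; each per-edge band crop
is resized to the edge network's input size, and the resulting traces are
mapped back through the composed geometry to original B-scan columns.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .boundary import (BoundaryTrace, CropGeometry, coarse_to_crop,
                       edge_map_to_trace, fill_trace_ends, map_trace_to_original)
from .coarse_seg import (CoarseLabelMap, CoarseModelConfig, CoarseUNet,
                         build_coarse_model, dilate_traces_to_labels,
                         predict_coarse, rasterize_trace, train_coarse)
from .edge_net import (EdgeMap, EdgeModelConfig, EdgeNet, build_edge_model,
                       predict_edge, train_edge)
from .evaluate import EvaluationReport, evaluate_dataset
from .phantom import EDGES, GroundTruthSet
from .preprocess import BilateralParams, bilateral_denoise
from .roi import ROIParams, crop_to_roi, define_roi

log = logging.getLogger(__name__)

EDGE_GROUP = {"ILM": "ILM", "RPE": "RPE/BM", "BM": "RPE/BM"}


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; defaults are the full-scale recipe."""

    bilateral: BilateralParams = field(default_factory=BilateralParams)
    roi: ROIParams = field(default_factory=ROIParams)
    coarse: CoarseModelConfig = field(default_factory=CoarseModelConfig)
    edge: EdgeModelConfig = field(default_factory=EdgeModelConfig)
    margin: int = 10
    threshold_frac: float = 0.3
    seed: int = 0

    def edge_config(self, edge_name: str) -> EdgeModelConfig:
        """Per-edge config: same architecture, distinct name and seed stream."""
        offset = {"ILM": 0, "RPE": 100, "BM": 200}[edge_name.upper()]
        return self.edge.replace(edge_name=edge_name.upper(),
                                 seed=self.edge.seed + offset)

    @classmethod
    def desk_scale(cls, seed: int = 0, coarse_epochs: int = 45,
                   edge_epochs: int = 25) -> "PipelineConfig":
        """Reduced-width, short-schedule protocol for CPU-scale phantoms.

        Keeps every structural choice of the full recipe (4-level coarse
        net, 6-block edge net, per-edge models) but shrinks channel widths,
        input sizes and the schedule so the whole cascade trains in minutes
        on one CPU core.  Adam replaces Adadelta here: the full-scale
        Adadelta recipe is tuned for a 300-epoch schedule and moves far too
        slowly in a few hundred optimization steps.  The coarse schedule is
        longer than the edge one: the thin ILM band takes ~40 epochs of soft
        Dice to separate from the inner retina, while the edge nets converge
        in ~20.
        """
        return cls(
            coarse=CoarseModelConfig(base_channels=4, epochs=coarse_epochs,
                                     optimizer="adam", lr=5e-3, decay=0.0,
                                     seed=seed),
            edge=EdgeModelConfig(input_size=(32, 256), width_mult=0.125,
                                 epochs=edge_epochs, optimizer="adam", lr=5e-3,
                                 decay=0.0, seed=seed + 1),
            seed=seed,
        )

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("bilateral", "roi", "coarse", "edge"):
            for k, v in d[key].items():
                if isinstance(v, tuple):
                    d[key][k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def tup(dd, *keys):
            for k in keys:
                if k in dd and isinstance(dd[k], list):
                    dd[k] = tuple(dd[k])
            return dd

        kw = dict(d)
        kw["bilateral"] = BilateralParams(**d.get("bilateral", {}))
        kw["roi"] = ROIParams(**d.get("roi", {}))
        kw["coarse"] = CoarseModelConfig(**tup(dict(d.get("coarse", {})), "input_size"))
        kw["edge"] = EdgeModelConfig(**tup(dict(d.get("edge", {})), "input_size"))
        return cls(**kw)


@dataclass
class PipelineModels:
    """Trained coarse model plus one edge model per boundary."""

    coarse: CoarseUNet
    edges: dict[str, EdgeNet]

    def validate(self) -> None:
        missing = [e for e in EDGES if e not in self.edges]
        if self.coarse is None or missing:
            raise ValueError(f"pipeline models incomplete: coarse="
                             f"{'ok' if self.coarse else 'missing'}, "
                             f"missing edge models {missing}")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.coarse.save(d / "coarse.npz")
        for name, m in self.edges.items():
            m.save(d / f"edge_{name.lower()}.npz")

    @classmethod
    def load(cls, directory: str | Path, cfg: PipelineConfig) -> "PipelineModels":
        d = Path(directory)
        for f in ["coarse.npz"] + [f"edge_{e.lower()}.npz" for e in EDGES]:
            if not (d / f).exists():
                raise FileNotFoundError(f"missing model checkpoint {d / f}")
        coarse = CoarseUNet.load(d / "coarse.npz", cfg.coarse)
        edges = {e: EdgeNet.load(d / f"edge_{e.lower()}.npz", cfg.edge_config(e))
                 for e in EDGES}
        return cls(coarse=coarse, edges=edges)


# ---------------------------------------------------------------------------
# shared stage helpers


def _resize_float(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    out = resize(img.astype(np.float32), size, order=1, preserve_range=True,
                 anti_aliasing=False)
    return (out / 255.0 if out.max() > 1.5 else out).astype(np.float32)


def prepare_scan(img: np.ndarray, cfg: PipelineConfig,
                 scan_id: str = "?") -> tuple[np.ndarray, CropGeometry]:
    """Denoise and crop one B-scan to its ROI; geometry has unit scale."""
    den = bilateral_denoise(img, cfg.bilateral)
    roi = define_roi(den, cfg.roi, scan_id=scan_id)
    crop, (r0, c0) = crop_to_roi(den, roi)
    return crop, CropGeometry(row_offset=r0, col_offset=c0)


def traces_in_crop(gt: GroundTruthSet, geom: CropGeometry,
                   crop_shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Ground-truth traces restricted to a unit-scale crop's coordinates."""
    c0 = geom.col_offset
    c1 = c0 + crop_shape[1]
    return {e: gt.trace(e)[c0:c1] - geom.row_offset for e in EDGES}


def _band_sample(crop: np.ndarray, labels: CoarseLabelMap, edge: str,
                 cfg: PipelineConfig) -> tuple[np.ndarray, CropGeometry]:
    """Per-edge band crop resized to the edge network input, with geometry."""
    band, bgeom = coarse_to_crop(crop, labels, EDGE_GROUP[edge], margin=cfg.margin)
    in_h, in_w = cfg.edge.input_size
    x = _resize_float(band, (in_h, in_w))
    geom = CropGeometry(row_offset=bgeom.row_offset, col_offset=bgeom.col_offset,
                        row_scale=in_h / band.shape[0], col_scale=in_w / band.shape[1])
    return x, geom


# ---------------------------------------------------------------------------
# training driver


def train_pipeline(scans: list[tuple[np.ndarray, GroundTruthSet]],
                   cfg: PipelineConfig,
                   progress: bool = False) -> tuple[PipelineModels, dict[str, list[float]]]:
    """Fit the coarse model, then the three edge models on its proposed bands.

    Edge models are trained on band crops produced by the *trained* coarse
    stage (as in deployment), with 1-px ground-truth polylines as targets.
    Returns the model bundle and the per-model loss histories.
    """
    if not scans:
        raise ValueError("no training scans")
    prepared = []
    for i, (img, gt) in enumerate(scans):
        crop, geom = prepare_scan(img, cfg, scan_id=f"train_{i:03d}")
        prepared.append((crop, geom, gt))

    size = cfg.coarse.input_size
    coarse_data = []
    for crop, geom, gt in prepared:
        tc = traces_in_crop(gt, geom, crop.shape)
        labels = dilate_traces_to_labels(
            GroundTruthSet(ilm=tc["ILM"], rpe=tc["RPE"], bm=tc["BM"]),
            src_shape=crop.shape, out_shape=size,
            element_size=cfg.coarse.label_element_size,
            iterations=cfg.coarse.label_dilation_iters)
        coarse_data.append((_resize_float(crop, size), labels))

    coarse = build_coarse_model(cfg.coarse)
    if progress:
        log.info("training coarse model on %d crops", len(coarse_data))
    histories = {"coarse": train_coarse(coarse, coarse_data, cfg.coarse)}

    # band samples from the trained coarse stage
    edge_data: dict[str, list] = {e: [] for e in EDGES}
    for crop, geom, gt in prepared:
        labels = predict_coarse(coarse, crop)
        tc = traces_in_crop(gt, geom, crop.shape)
        for edge in EDGES:
            x, bgeom = _band_sample(crop, labels, edge, cfg)
            band_h = int(round(cfg.edge.input_size[0] / bgeom.row_scale))
            band_w = int(round(cfg.edge.input_size[1] / bgeom.col_scale))
            t = tc[edge][bgeom.col_offset:bgeom.col_offset + band_w] - bgeom.row_offset
            raster = rasterize_trace(t, (band_h, band_w), cfg.edge.input_size)
            edge_data[edge].append((x, raster.astype(np.float32)))

    edges = {}
    for edge in EDGES:
        ecfg = cfg.edge_config(edge)
        model = build_edge_model(ecfg)
        if progress:
            log.info("training %s edge model on %d bands", edge, len(edge_data[edge]))
        histories[f"edge_{edge}"] = train_edge(model, edge_data[edge], ecfg)
        edges[edge] = model
    return PipelineModels(coarse=coarse, edges=edges), histories


# ---------------------------------------------------------------------------
# inference


def segment_scan(img: np.ndarray, models: PipelineModels, cfg: PipelineConfig,
                 scan_id: str = "?") -> dict[str, BoundaryTrace]:
    """Run the full cascade on one B-scan; returns full-width traces per edge."""
    models.validate()
    h, w = img.shape
    crop, roi_geom = prepare_scan(img, cfg, scan_id=scan_id)
    labels = predict_coarse(models.coarse, crop)
    out = {}
    for edge in EDGES:
        x, bgeom = _band_sample(crop, labels, edge, cfg)
        em = predict_edge(models.edges[edge], x)
        tr = edge_map_to_trace(em, threshold_frac=cfg.threshold_frac)
        full_geom = bgeom.compose(roi_geom)
        tr = map_trace_to_original(tr, full_geom, out_width=w, image_height=h)
        out[edge] = fill_trace_ends(tr)
    return out


def band_recall(img: np.ndarray, gt: GroundTruthSet, models: PipelineModels,
                cfg: PipelineConfig) -> dict[str, float]:
    """Fraction of columns whose true boundary falls inside the proposed band crop.

    Measures the coarse stage as a region proposer: for each edge, the
    fraction of all B-scan columns where (column, true row) lies within the
    per-edge band crop handed to the fine network.
    """
    w = img.shape[1]
    crop, roi_geom = prepare_scan(img, cfg)
    labels = predict_coarse(models.coarse, crop)
    out = {}
    for edge in EDGES:
        band, bgeom = coarse_to_crop(crop, labels, EDGE_GROUP[edge], margin=cfg.margin)
        r0 = roi_geom.row_offset + bgeom.row_offset
        r1 = r0 + band.shape[0]
        c0 = roi_geom.col_offset + bgeom.col_offset
        c1 = c0 + band.shape[1]
        rows = gt.trace(edge)
        cols = np.arange(w)
        inside = (cols >= c0) & (cols < c1) & (rows >= r0) & (rows < r1)
        out[edge] = float(inside.mean())
    return out


def run_pipeline(scans: dict[str, np.ndarray], models: PipelineModels,
                 cfg: PipelineConfig,
                 gt: dict[str, GroundTruthSet] | None = None,
                 groups: dict[str, str] | None = None,
                 ) -> tuple[dict[str, dict[str, BoundaryTrace]], EvaluationReport | None]:
    """Segment many scans; optionally evaluate against ground truth.

    ``scans`` maps scan_id -> image.  When ``gt`` is given a report is
    computed (groups default to a single group "all-scans").
    """
    models.validate()
    traces = {}
    for sid, img in scans.items():
        try:
            traces[sid] = segment_scan(img, models, cfg, scan_id=sid)
        except Exception as e:
            raise RuntimeError(f"pipeline failed on scan {sid!r}: {e}") from e
    report = None
    if gt is not None:
        gt_traces = {sid: {e: BoundaryTrace(rows=g.trace(e)) for e in EDGES}
                     for sid, g in gt.items()}
        if groups is None:
            groups = {sid: "all-scans" for sid in gt_traces}
        report = evaluate_dataset(traces, gt_traces, groups)
    return traces, report
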