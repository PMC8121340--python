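"""Stage-2 fine segmentation: a dense-inception style multi-scale edge
detector (DexiNed family) that turns a band crop into a thin edge-probability
map for one boundary.

The encoder is a chain of six main blocks; each block stacks two 3x3
convolutions with batch normalization and ReLU (the last sub-block
convolutions carry no activation) and blocks are separated by 3x3 stride-2
max pooling.  From block 3 onward the sub-block output is averaged with a
1x1-projected border connection of the block input, which keeps edge
evidence alive at depth.  Every block feeds its own (non-weight-shared)
upsampling head — a 1x1 channel collapse followed by a chain of stride-2
transposed convolutions — producing six side edge maps at input resolution;
a learned 1x1 fusion over the concatenated side maps yields the fused map.

One model is trained per boundary (ILM, RPE, BM).  The loss is the
class-balanced cross-entropy used for thin-edge detection: with
beta = |Y-|/|Y| the fraction of non-edge pixels (typically 0.85-0.90 here),
edge pixels are weighted by beta and background pixels by 1-beta, summed
over the six side outputs plus the fused output.

Spatial sizes must be multiples of 16.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.optim import make_optimizer

EPS = 1e-7

#: published encoder widths; desk-scale runs shrink these via ``width_mult``
FULL_WIDTHS = (32, 64, 128, 256, 512, 512)


@dataclass(frozen=True)
class EdgeModelConfig:
    """Edge-network topology and training recipe for one boundary.

    ``input_size`` is (rows, cols); the full-scale default (128, 992) is the
    aspect-distorting resize of a 512 x 1000 B-scan band.  Both dimensions
    must be multiples of 16 (five stride-2 poolings inside the encoder).
    """

    input_size: tuple[int, int] = (128, 992)
    n_main_blocks: int = 6
    width_mult: float = 1.0
    beta_weighting: bool = True
    epochs: int = 300
    batch_size: int = 4
    optimizer: str = "adadelta"
    lr: float = 1e-4
    decay: float = 0.095
    seed: int = 0
    edge_name: str = "ILM"

    def validate(self) -> None:
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(
                f"edge-network input {h}x{w} invalid: both sides must be "
                "multiples of 16")
        if self.edge_name.upper() not in ("ILM", "RPE", "BM"):
            raise ValueError(f"unknown edge name {self.edge_name!r}")
        if self.n_main_blocks < 2:
            raise ValueError("need at least 2 main blocks")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(max(2, int(round(w * self.width_mult)))
                     for w in FULL_WIDTHS[: self.n_main_blocks])

    def replace(self, **kw) -> "EdgeModelConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EdgeMap:
    """Fused edge-probability image plus the per-block side maps, all in [0, 1]."""

    fused: np.ndarray
    side_maps: list[np.ndarray]


class _SubBlock:
    """Two 3x3 convs with BN; ReLU after the first only when ``final`` is set."""

    def __init__(self, cin, cout, rng, final: bool):
        self.layers = [nn.Conv2d(cin, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU(),
                       nn.Conv2d(cout, cout, 3, rng), nn.BatchNorm2d(cout)]
        if not final:
            self.layers.append(nn.ReLU())

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def params(self):
        return [p for l in self.layers for p in l.params()]


class _UpHead:
    """1x1 collapse to one channel, then stride-2 transposed convs up to full size."""

    def __init__(self, cin, n_up, rng):
        self.collapse = nn.Conv2d(cin, 1, 1, rng)
        self.ups = [nn.ConvTranspose2d(1, 1, rng) for _ in range(n_up)]
        self._crop = None

    def forward(self, x, target_hw, train):
        x = self.collapse.forward(x, train)
        for up in self.ups:
            x = up.forward(x, train)
        h, w = x.shape[2], x.shape[3]
        th, tw = target_hw
        self._crop = (h, w)
        return x[:, :, :th, :tw]

    def backward(self, g):
        h, w = self._crop
        if (h, w) != g.shape[2:]:
            gp = np.zeros(g.shape[:2] + (h, w), dtype=g.dtype)
            gp[:, :, :g.shape[2], :g.shape[3]] = g
            g = gp
        for up in reversed(self.ups):
            g = up.backward(g)
        return self.collapse.backward(g)

    def params(self):
        return self.collapse.params() + [p for u in self.ups for p in u.params()]


class EdgeNet:
    """Multi-scale edge detector: 6 main blocks, 6 side heads, learned fusion."""

    def __init__(self, cfg: EdgeModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.widths
        nb = cfg.n_main_blocks
        self.blocks: list[_SubBlock] = []
        self.projections: list[nn.Conv2d | None] = []
        cin = 1
        for b in range(nb):
            self.blocks.append(_SubBlock(cin, widths[b], rng, final=(b == nb - 1)))
            # border connection from block 3 on: 1x1 projection of the block input
            if b >= 2:
                self.projections.append(nn.Conv2d(cin, widths[b], 1, rng))
            else:
                self.projections.append(None)
            cin = widths[b]
        self.pools = [nn.MaxPool2d() for _ in range(nb - 1)]
        self.heads = [_UpHead(widths[b], b, rng) for b in range(nb)]
        self.fuse = nn.Conv2d(nb, 1, 1, rng)
        self._cache = None

    def params(self):
        ps = []
        for blk, proj in zip(self.blocks, self.projections):
            ps += blk.params()
            if proj is not None:
                ps += proj.params()
        for h in self.heads:
            ps += h.params()
        ps += self.fuse.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.v.size for p in self.params())

    def forward_logits(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Return the 7 logit maps (6 side + fused), each (B,1,H,W)."""
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input {h}x{w} must have sides divisible by 16")
        target = (h, w)
        side_logits = []
        for b, blk in enumerate(self.blocks):
            s = blk.forward(x, train)
            proj = self.projections[b]
            if proj is not None:
                s = 0.5 * (s + proj.forward(x, train))
            side_logits.append(self.heads[b].forward(s, target, train))
            if b < len(self.pools):
                x = self.pools[b].forward(s, train)
        cat = np.concatenate(side_logits, axis=1)
        self._cat = cat if train else None
        fused_logit = self.fuse.forward(cat, train)
        return side_logits + [fused_logit]

    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Sigmoid probabilities for the 7 outputs."""
        return [nn.sigmoid(z) for z in self.forward_logits(x, train)]

    def backward(self, gside: list[np.ndarray], gfused: np.ndarray) -> None:
        """Backprop given gradients wrt the 6 side logits and the fused logit."""
        gcat = self.fuse.backward(gfused)
        gsides = [gside[b] + gcat[:, b:b + 1] for b in range(len(self.blocks))]
        gx_next = None  # gradient flowing into block b's output via the pool chain
        for b in reversed(range(len(self.blocks))):
            gs = self.heads[b].backward(gsides[b])
            if gx_next is not None:
                gs = gs + gx_next
            proj = self.projections[b]
            if proj is not None:
                gin_proj = proj.backward(0.5 * gs)
                gin_blk = self.blocks[b].backward(0.5 * gs)
                gin = gin_blk + gin_proj
            else:
                gin = self.blocks[b].backward(gs)
            gx_next = self.pools[b - 1].backward(gin) if b > 0 else None

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.v for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn{i}_mean"] = bn.running_mean
            state[f"bn{i}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state) -> None:
        for i, p in enumerate(self.params()):
            p.v[...] = state[f"p{i}"]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"bn{i}_mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"bn{i}_var"], dtype=np.float32)

    def _batchnorms(self):
        return [l for blk in self.blocks for l in blk.layers
                if isinstance(l, nn.BatchNorm2d)]

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    @classmethod
    def load(cls, path, cfg: EdgeModelConfig) -> "EdgeNet":
        model = cls(cfg)
        with np.load(path) as st:
            model.load_state_arrays(dict(st))
        return model


def build_edge_model(cfg: EdgeModelConfig) -> EdgeNet:
    return EdgeNet(cfg)


def weighted_edge_loss(pred: np.ndarray | list[np.ndarray], truth: np.ndarray,
                       per_output_weights: list[float] | None = None) -> float:
    """Class-balanced cross-entropy for thin-edge maps.

    For each output, with beta = |Y-|/|Y| the non-edge fraction:
    loss = -beta * sum_{edge px} log p - (1-beta) * sum_{non-edge px} log(1-p).
    ``pred`` may be one probability map or the list of 7 outputs; weights
    default to 1.0 per output.  Probabilities are clipped to [eps, 1-eps].
    An all-background truth makes the positive term empty and the negative
    weight zero — degenerate; a warning is raised and 0 returned (training
    skips such samples).
    """
    preds = pred if isinstance(pred, list) else [pred]
    truth = np.asarray(truth)
    uniq = np.unique(truth)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"truth must be binary, found values {uniq[:8]}")
    if per_output_weights is None:
        per_output_weights = [1.0] * len(preds)
    y = truth.astype(np.float64)
    n_pos = y.sum()
    beta = 1.0 - n_pos / y.size
    if n_pos == 0:
        warnings.warn("weighted_edge_loss: truth has no edge pixels; "
                      "beta weighting degenerates, returning 0", stacklevel=2)
        return 0.0
    total = 0.0
    for wgt, p in zip(per_output_weights, preds):
        p = np.clip(np.asarray(p, dtype=np.float64).reshape(truth.shape), EPS, 1 - EPS)
        total += wgt * float(-(beta * (y * np.log(p)).sum()
                               + (1 - beta) * ((1 - y) * np.log(1 - p)).sum()))
    return total


def _edge_loss_and_grads(logit_maps: list[np.ndarray], y: np.ndarray,
                         weights: list[float]) -> tuple[float, list[np.ndarray]]:
    """Loss plus gradients wrt each logit map for a batch.

    y: (B,1,H,W) binary.  beta is computed per sample.  Gradient of the
    balanced BCE wrt the logit z is beta*(p-1) on edges and (1-beta)*p off
    edges (scaled by the per-output weight).
    """
    B = y.shape[0]
    n_px = y.shape[2] * y.shape[3]
    pos = y.sum(axis=(1, 2, 3), keepdims=True)
    beta = 1.0 - pos / n_px
    total = 0.0
    grads = []
    for wgt, z in zip(weights, logit_maps):
        p = nn.sigmoid(z).astype(np.float64)
        pc = np.clip(p, EPS, 1 - EPS)
        total += wgt * float(-(beta * y * np.log(pc)
                               + (1 - beta) * (1 - y) * np.log(1 - pc)).sum())
        g = wgt * (beta * y * (p - 1.0) + (1 - beta) * (1 - y) * p)
        grads.append(g.astype(np.float32))
    return total / B, [g / B for g in grads]


def train_edge(model: EdgeNet, dataset: list[tuple[np.ndarray, np.ndarray]],
               cfg: EdgeModelConfig | None = None,
               checkpoint=None) -> list[float]:
    """Train one per-boundary edge model; returns per-epoch mean loss.

    ``dataset``: (image, edge raster) pairs at ``cfg.input_size``, image float
    in [0,1], raster binary with the boundary as a 1-px polyline.  Samples
    whose raster has no edge pixels degenerate the balanced loss and are
    dropped with a warning.
    """
    cfg = cfg or model.cfg
    if not dataset:
        raise ValueError("empty training dataset")
    kept = []
    for i, (img, raster) in enumerate(dataset):
        if np.asarray(raster).sum() == 0:
            warnings.warn(f"train_edge[{cfg.edge_name}]: sample {i} has no edge "
                          "pixels; skipped", stacklevel=2)
            continue
        kept.append((img, raster))
    if not kept:
        raise ValueError("no trainable samples: every raster was empty")
    xs = np.stack([np.asarray(i, dtype=np.float32)[None] for i, _ in kept])
    ys = np.stack([np.asarray(r, dtype=np.float64)[None] for _, r in kept])
    n_out = len(model.blocks) + 1
    weights = [1.0] * n_out
    rng = np.random.default_rng(cfg.seed + 2)
    opt = make_optimizer(cfg.optimizer, model.params(), lr=cfg.lr, decay=cfg.decay)
    history = []
    n = len(kept)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            logits = model.forward_logits(xs[idx], train=True)
            loss, grads = _edge_loss_and_grads(logits, ys[idx], weights)
            opt.zero_grad()
            model.backward(grads[:-1], grads[-1])
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    if checkpoint is not None:
        model.save(checkpoint)
    return history


def predict_edge(model: EdgeNet, crop: np.ndarray) -> EdgeMap:
    """Run the edge net on one crop already resized to ``cfg.input_size``."""
    crop = np.asarray(crop, dtype=np.float32)
    if crop.max() > 1.5:
        crop = crop / 255.0
    if crop.shape != model.cfg.input_size:
        raise ValueError(f"crop shape {crop.shape} != configured input "
                         f"{model.cfg.input_size}; resize first (predict_on_band)")
    probs = model.forward(crop[None, None], train=False)
    return EdgeMap(fused=probs[-1][0, 0], side_maps=[p[0, 0] for p in probs[:-1]])
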