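"""Stage-1 coarse segmentation: a small encoder-decoder (U-Net) that locates
the ILM band and the RPE/BM band inside the ROI crop.

The network sees the ROI crop resized to ``input_size`` (128 x 128 by
default) and predicts one of four classes per pixel: 0 background ("bottom"),
1 ILM border band, 2 RPE border band, 3 BM border band.  Because a 1-px
boundary polyline would vanish under four rounds of downsampling, the
ground-truth traces are rasterized and then morphologically dilated into
bands before training.  Training minimizes a soft multi-class Dice loss
(unweighted mean of the per-foreground-class soft Dice losses).

The coarse stage is only a region proposer: its output bands are turned into
per-edge crops for the fine edge network, so the quantity that matters is
band recall of the true trace, not boundary accuracy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .nn.optim import make_optimizer
from .phantom import GroundTruthSet

CLASS_NAMES = ("bottom", "ILM", "RPE", "BM")


@dataclass(frozen=True)
class CoarseModelConfig:
    """U-Net topology plus the training recipe.

    The training defaults (300 epochs, batch 4, Adadelta, lr 1e-4, decay
    0.095) are the full-scale recipe; desk-scale runs override epochs, width
    and learning rate (see the training protocol in the docs).
    """

    levels: int = 4
    base_channels: int = 16
    dropout: float = 0.2
    input_size: tuple[int, int] = (128, 128)
    n_classes: int = 4
    epochs: int = 300
    batch_size: int = 4
    optimizer: str = "adadelta"
    lr: float = 1e-4
    decay: float = 0.095
    seed: int = 0
    label_element_size: int = 3
    label_dilation_iters: int = 2

    def validate(self) -> None:
        h, w = self.input_size
        if h != w:
            raise ValueError(f"coarse input must be square, got {self.input_size}")
        if h % (2 ** self.levels):
            raise ValueError(
                f"input size {h} not divisible by 2^{self.levels}; "
                "the encoder halves resolution once per level"
            )

    def replace(self, **kw) -> "CoarseModelConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class CoarseLabelMap:
    """Integer class image; values in {0 bottom, 1 ILM, 2 RPE, 3 BM}."""

    labels: np.ndarray


def rasterize_trace(trace: np.ndarray, src_shape: tuple[int, int],
                    out_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a per-column trace (src coords) to a 1-px polyline mask.

    The trace is resampled to the output width and drawn with vertical
    connectivity (adjacent columns are joined through the midpoint) so steep
    segments stay 8-connected.
    """
    sh, sw = src_shape
    oh, ow = out_shape
    trace = np.asarray(trace, dtype=np.float64)
    if len(trace) != sw:
        raise ValueError(f"trace length {len(trace)} != source width {sw}")
    # pixel-center resample of columns, then row rescale
    xs = (np.arange(ow) + 0.5) * sw / ow - 0.5
    rows = np.interp(xs, np.arange(sw), trace) * (oh / sh)
    if np.all(rows < -0.5) or np.all(rows > oh - 0.5):
        raise ValueError("trace lies entirely outside the target raster")
    mask = np.zeros((oh, ow), dtype=bool)
    r = np.clip(np.round(rows).astype(int), 0, oh - 1)
    for j in range(ow):
        lo, hi = r[j], r[j]
        if j > 0:
            mid = int(np.round((r[j - 1] + r[j]) / 2))
            lo, hi = min(lo, mid), max(hi, mid)
        if j < ow - 1:
            mid = int(np.round((r[j + 1] + r[j]) / 2))
            lo, hi = min(lo, mid), max(hi, mid)
        mask[lo:hi + 1, j] = True
    return mask


def dilate_traces_to_labels(gt: GroundTruthSet, src_shape: tuple[int, int],
                            out_shape: tuple[int, int] = (128, 128),
                            element_size: int = 3,
                            iterations: int = 2) -> CoarseLabelMap:
    """Build the 4-class label map from ground-truth traces in crop coordinates.

    Each trace is rasterized at ``out_shape`` and dilated ``iterations`` times
    with a square ``element_size`` element.  Overlaps are resolved in favor of
    the later class (ILM < RPE < BM priority), so every pixel has one label.
    """
    labels = np.zeros(out_shape, dtype=np.int64)
    struct = np.ones((element_size, element_size), dtype=bool)
    for cls, trace in ((1, gt.ilm), (2, gt.rpe), (3, gt.bm)):
        band = rasterize_trace(trace, src_shape, out_shape)
        if iterations > 0:
            band = ndimage.binary_dilation(band, structure=struct, iterations=iterations)
        labels[band] = cls
    return CoarseLabelMap(labels=labels)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return (labels[..., None] == np.arange(n_classes)).astype(np.float32)


def dice_loss(pred: np.ndarray, truth: CoarseLabelMap | np.ndarray,
              n_classes: int = 4) -> float:
    """Soft multi-class Dice loss 1 - 2*VP / (2*VP + FP + FN).

    ``pred`` is a per-pixel class probability map with the class axis last,
    shape (H, W, C); ``truth`` an integer label map.  Counts are
    probability-weighted; the loss is the unweighted mean over foreground
    classes (1..C-1) and lies in [0, 1].
    """
    truth_arr = truth.labels if isinstance(truth, CoarseLabelMap) else np.asarray(truth)
    pred = np.asarray(pred, dtype=np.float64)
    if pred.shape[:-1] != truth_arr.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape[:-1]} vs truth {truth_arr.shape}")
    onehot = _one_hot(truth_arr, n_classes)
    losses = []
    for c in range(1, n_classes):
        p, y = pred[..., c], onehot[..., c]
        vp = float((p * y).sum())
        denom = float(p.sum() + y.sum())  # == 2VP + FP + FN for soft counts
        losses.append(0.0 if denom == 0 else 1.0 - 2.0 * vp / denom)
    return float(np.mean(losses))


def _dice_loss_grad(probs: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-batch soft Dice loss and gradient wrt probabilities.

    probs, onehot: (B, C, H, W).  Loss averages over samples and foreground
    classes; gradient matches that normalization.
    """
    B, C = probs.shape[:2]
    fg = C - 1
    grad = np.zeros_like(probs)
    total = 0.0
    for b in range(B):
        for c in range(1, C):
            p, y = probs[b, c], onehot[b, c]
            vp = (p * y).sum()
            denom = p.sum() + y.sum()
            if denom == 0:
                continue
            total += 1.0 - 2.0 * vp / denom
            grad[b, c] = -2.0 * (y * denom - vp) / (denom * denom)
    norm = B * fg
    return total / norm, grad / norm


class _ConvBlock:
    """conv3x3-BN-ReLU twice, then dropout."""

    def __init__(self, cin, cout, dropout, rng, drop_rng):
        self.layers = [
            nn.Conv2d(cin, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Dropout(dropout, drop_rng),
        ]

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


class CoarseUNet:
    """Canonical U-Net with average-pool downsampling and transposed-conv upsampling."""

    def __init__(self, cfg: CoarseModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.drop_rng = np.random.default_rng(cfg.seed + 1)
        B = cfg.base_channels
        L = cfg.levels
        chans = [B * (2 ** i) for i in range(L + 1)]
        self.enc = []
        cin = 1
        for i in range(L):
            self.enc.append(_ConvBlock(cin, chans[i], cfg.dropout, rng, self.drop_rng))
            cin = chans[i]
        self.pools = [nn.AvgPool2d() for _ in range(L)]
        self.bottleneck = _ConvBlock(chans[L - 1], chans[L], cfg.dropout, rng, self.drop_rng)
        self.ups = []
        self.dec = []
        for i in reversed(range(L)):
            self.ups.append(nn.ConvTranspose2d(chans[i + 1], chans[i], rng))
            self.dec.append(_ConvBlock(2 * chans[i], chans[i], cfg.dropout, rng, self.drop_rng))
        self.head = nn.Conv2d(chans[0], cfg.n_classes, 1, rng)
        self._skip_channels = None

    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for up, blk in zip(self.ups, self.dec):
            ps += up.params() + blk.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(B,1,H,W) float32 -> (B,n_classes,H,W) per-pixel class probabilities."""
        h, w = x.shape[2], x.shape[3]
        if h % (2 ** self.cfg.levels) or w % (2 ** self.cfg.levels):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{self.cfg.levels}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        logits = self.head.forward(x, train)
        probs = nn.softmax_channel(logits)
        if train:
            self._probs = probs
        return probs

    def backward(self, gprobs: np.ndarray) -> None:
        g = nn.softmax_backward(self._probs, gprobs)
        g = self.head.backward(g)
        # dec[i] consumed skips[L-1-i]; walk the decoder back toward the bottleneck
        L = len(self.dec)
        gskips = [None] * L
        for i in reversed(range(L)):
            g = self.dec[i].backward(g)
            ch = self._skip_channels[L - 1 - i]
            gskips[L - 1 - i], g = g[:, :ch], g[:, ch:]
            g = self.ups[i].backward(g)
        g = self.bottleneck.backward(g)
        for i in reversed(range(len(self.enc))):
            g = self.pools[i].backward(g)
            g = g + gskips[i]
            g = self.enc[i].backward(g)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.v for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn{i}_mean"] = bn.running_mean
            state[f"bn{i}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.v[...] = state[f"p{i}"]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"bn{i}_mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"bn{i}_var"], dtype=np.float32)

    def _batchnorms(self):
        bns = []
        blocks = self.enc + [self.bottleneck] + self.dec
        for blk in blocks:
            bns += [l for l in blk.layers if isinstance(l, nn.BatchNorm2d)]
        return bns

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path, cfg: CoarseModelConfig) -> "CoarseUNet":
        model = cls(cfg)
        with np.load(path) as st:
            model.load_state_arrays(dict(st))
        return model


def build_coarse_model(cfg: CoarseModelConfig) -> CoarseUNet:
    return CoarseUNet(cfg)


def train_coarse(model: CoarseUNet, dataset: list[tuple[np.ndarray, CoarseLabelMap]],
                 cfg: CoarseModelConfig | None = None,
                 checkpoint: str | Path | None = None) -> list[float]:
    """Train on (image, label map) pairs; returns per-epoch mean Dice loss.

    Images are (H, W) float arrays in [0, 1] at ``cfg.input_size``; all
    shuffling and dropout derive from ``cfg.seed``.
    """
    cfg = cfg or model.cfg
    if not dataset:
        raise ValueError("empty training dataset")
    C = cfg.n_classes
    xs = np.stack([np.asarray(img, dtype=np.float32)[None] for img, _ in dataset])
    ys = np.stack([
        _one_hot(lm.labels if isinstance(lm, CoarseLabelMap) else lm, C)
        .transpose(2, 0, 1) for _, lm in dataset
    ])
    rng = np.random.default_rng(cfg.seed + 2)
    opt = make_optimizer(cfg.optimizer, model.params(), lr=cfg.lr, decay=cfg.decay)
    history = []
    n = len(dataset)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            probs = model.forward(xs[idx], train=True)
            loss, gp = _dice_loss_grad(probs.astype(np.float64), ys[idx])
            opt.zero_grad()
            model.backward(gp.astype(np.float32))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    if checkpoint is not None:
        model.save(checkpoint)
    return history


def predict_coarse(model: CoarseUNet, crop: np.ndarray) -> CoarseLabelMap:
    """Predict the 4-class label map for a ROI crop, at crop resolution."""
    crop = np.asarray(crop)
    h, w = crop.shape
    size = model.cfg.input_size
    x = resize(crop.astype(np.float32), size, order=1, preserve_range=True,
               anti_aliasing=False)
    if crop.dtype == np.uint8 or x.max() > 1.5:
        x = x / 255.0
    probs = model.forward(x[None, None].astype(np.float32), train=False)
    labels_small = probs[0].argmax(axis=0)
    labels = resize(labels_small.astype(np.float32), (h, w), order=0,
                    preserve_range=True, anti_aliasing=False).astype(np.int64)
    return CoarseLabelMap(labels=labels)
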