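"""Layers with explicit forward/backward passes (float32, NCHW)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' zero padding (p = k // 2), He init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k, self.cin, self.cout = k, cin, cout
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp if train else None
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,Ci,H,W,k,k
        out = np.einsum("bihwuv,oiuv->bohw", win, self.W.v, optimize=True)
        return out + self.b.v[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = self._xp
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        self.W.g += np.einsum("bihwuv,bohw->oiuv", win, gy, optimize=True)
        self.b.g += gy.sum(axis=(0, 2, 3))
        # full correlation of gy with the flipped kernel gives grad wrt padded x
        gyp = np.pad(gy, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        gwin = sliding_window_view(gyp, (k, k), axis=(2, 3))
        Wf = self.W.v[:, :, ::-1, ::-1]
        gxp = np.einsum("bohwuv,oiuv->bihw", gwin, Wf, optimize=True)
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return np.ascontiguousarray(gxp)


class ConvTranspose2d(Layer):
    """2x upsampling transposed convolution with kernel 2, stride 2 (exact doubling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (cin * 4))
        self.W = Param(rng.normal(0.0, std, size=(cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        B, C, H, W = x.shape
        t = np.einsum("bchw,couv->bohuwv", x, self.W.v, optimize=True)
        out = t.reshape(B, self.cout, 2 * H, 2 * W)
        return out + self.b.v[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        B, C, H, W = x.shape
        g = gy.reshape(B, self.cout, H, 2, W, 2)
        self.W.g += np.einsum("bchw,bohuwv->couv", x, g, optimize=True)
        self.b.g += gy.sum(axis=(0, 2, 3))
        return np.einsum("bohuwv,couv->bchw", g, self.W.v, optimize=True)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.g += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += gy.sum(axis=(0, 2, 3))
        N = gy.shape[0] * gy.shape[2] * gy.shape[3]
        gxhat = gy * self.gamma.v[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        t = inv[None, :, None, None]
        return (gxhat - s1 / N - xhat * s2 / N) * t


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Dropout(Layer):
    """Inverted dropout; draws its masks from a shared seeded generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        self._mask = mask
        return x * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class MaxPool2d(Layer):
    """3x3 max pooling, stride 2, pad 1 — output spatial size is ceil(in / 2)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        ph = 1 + (H % 2)   # right/bottom padding so windows cover ceil(H/2) steps
        pw = 1 + (W % 2)
        xp = np.pad(x, ((0, 0), (0, 0), (1, ph), (1, pw)), constant_values=-np.inf)
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::2, ::2]
        Ho, Wo = win.shape[2], win.shape[3]
        flat = win.reshape(B, C, Ho, Wo, 9)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (B, C, H, W), (Ho, Wo))
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, (B, C, H, W), (Ho, Wo) = self._cache
        gx = np.zeros((B, C, H + 2, W + 2), dtype=gy.dtype)  # generous pad, cropped below
        bi, ci, ii, ji = np.ix_(np.arange(B), np.arange(C), np.arange(Ho), np.arange(Wo))
        rows = 2 * ii + idx // 3          # in padded coords (pad=1 each side)
        cols = 2 * ji + idx % 3
        np.add.at(gx, (bi, ci, rows, cols), gy)
        return gx[:, :, 1:H + 1, 1:W + 1]


class AvgPool2d(Layer):
    """2x2 average pooling, stride 2; requires even spatial sizes."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"AvgPool2d needs even spatial size, got {H}x{W}")
        if train:
            self._shape = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        return np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) * 0.25


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_channel(z: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of an NCHW tensor."""
    m = z.max(axis=1, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(p: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Gradient through channel softmax: dL/dz given p = softmax(z) and dL/dp."""
    dot = (gp * p).sum(axis=1, keepdims=True)
    return p * (gp - dot)
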