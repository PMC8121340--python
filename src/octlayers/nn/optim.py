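"""Optimizers.

Adadelta follows the Keras-legacy formulation (per-parameter accumulators of
squared gradients and squared updates, ratio step) with an optional
per-iteration learning-rate decay lr_t = lr0 / (1 + decay * t), the scheme
used by the Keras stack this pipeline's training recipe comes from.  Adam is
provided as an alternative for quick experiments.
"""

from __future__ import annotations

import numpy as np

from .layers import Param


class Optimizer:
    def __init__(self, params: list[Param]):
        self.params = params

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class Adadelta(Optimizer):
    def __init__(self, params: list[Param], lr: float = 1.0, rho: float = 0.95,
                 eps: float = 1e-7, decay: float = 0.0):
        super().__init__(params)
        self.lr0, self.rho, self.eps, self.decay = lr, rho, eps, decay
        self.t = 0
        self.Eg = [np.zeros_like(p.v) for p in params]
        self.Edx = [np.zeros_like(p.v) for p in params]

    def step(self) -> None:
        lr = self.lr0 / (1.0 + self.decay * self.t)
        self.t += 1
        for p, eg, edx in zip(self.params, self.Eg, self.Edx):
            g = p.g
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt(edx + self.eps) / np.sqrt(eg + self.eps) * g
            edx *= self.rho
            edx += (1 - self.rho) * dx * dx
            p.v += (lr * dx).astype(np.float32)


class Adam(Optimizer):
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, decay: float = 0.0):
        super().__init__(params)
        self.lr0, self.b1, self.b2, self.eps, self.decay = lr, beta1, beta2, eps, decay
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def step(self) -> None:
        lr = self.lr0 / (1.0 + self.decay * self.t)
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.g
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.v -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(np.float32)


def make_optimizer(name: str, params: list[Param], lr: float, decay: float = 0.0) -> Optimizer:
    name = name.lower()
    if name == "adadelta":
        return Adadelta(params, lr=lr, decay=decay)
    if name == "adam":
        return Adam(params, lr=lr, decay=decay)
    raise ValueError(f"unknown optimizer {name!r}")
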