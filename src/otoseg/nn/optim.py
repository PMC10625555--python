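"""Optimizers: AdamW with decoupled weight decay, and SGD with momentum.

Weight decay is applied directly to the parameters (multiplicative shrink by
``lr * weight_decay`` per step) rather than being added to the loss, so the
regularization term never contaminates the logged loss components.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

_F32 = np.float32


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class AdamW(Optimizer):
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.025,
    ):
        super().__init__(params, lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.weight_decay:
                p.data -= p.data.dtype.type(self.lr * self.weight_decay) * p.data
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.data -= step.astype(p.data.dtype)


class SGD(Optimizer):
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-2,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self.weight_decay:
                p.data -= p.data.dtype.type(self.lr * self.weight_decay) * p.data
            self.buf[i] = self.momentum * self.buf[i] + p.grad
            p.data -= (self.lr * self.buf[i]).astype(p.data.dtype)


def make_optimizer(name: str, params, lr: float, weight_decay: float = 0.025,
                   betas=(0.9, 0.999), momentum: float = 0.9) -> Optimizer:
    if name == "adamw":
        return AdamW(params, lr=lr, betas=betas, weight_decay=weight_decay)
    if name == "sgd":
        return SGD(params, lr=lr, momentum=momentum, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}; choose 'adamw' or 'sgd'")
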