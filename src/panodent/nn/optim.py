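"""Optimizers for the NumPy autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with optional per-step learning-rate schedule."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, step: int, total_steps: int,
              min_fraction: float = 0.05) -> float:
    """Cosine decay from ``base_lr`` to ``min_fraction * base_lr``."""
    if total_steps <= 1:
        return base_lr
    frac = min(step, total_steps - 1) / (total_steps - 1)
    scale = min_fraction + (1.0 - min_fraction) * 0.5 * (1.0 + np.cos(np.pi * frac))
    return base_lr * scale
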