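"""Rectified Adam and the warm-up + cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Parameter

__all__ = ["RAdam", "WarmupCosine"]


class RAdam:
    """Rectified Adam (Liu et al. variance-rectification rule)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1t, b2t = self.b1**t, self.b2**t
        rho = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        if rho > 4.0:
            r = math.sqrt(
                (rho - 4.0)
                * (rho - 2.0)
                * self.rho_inf
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
            )
        else:
            r = None
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            m_hat = self.m[i] / (1.0 - b1t)
            if r is not None:
                v_hat = np.sqrt(self.v[i] / (1.0 - b2t))
                p.data = p.data - self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data = p.data - self.lr * m_hat


class WarmupCosine:
    """Linear warm-up to ``lr_start`` followed by cosine decay to ``lr_min``."""

    def __init__(self, lr_start: float, lr_min: float, warmup_steps: int, total_steps: int):
        if total_steps < 1:
            raise ValueError("total_steps must be positive")
        self.lr_start = lr_start
        self.lr_min = lr_min
        self.warmup = max(0, int(warmup_steps))
        self.total = int(total_steps)

    def __call__(self, it: int) -> float:
        if self.warmup and it < self.warmup:
            return self.lr_start * (it + 1) / self.warmup
        span = max(1, self.total - self.warmup)
        frac = min(1.0, (it - self.warmup) / span)
        return self.lr_min + 0.5 * (self.lr_start - self.lr_min) * (
            1.0 + math.cos(math.pi * frac)
        )
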