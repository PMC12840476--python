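"""Optimisation: AdamW with decoupled weight decay and a cosine-annealing
learning-rate schedule with warm restarts."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 5e-2,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_warm_restarts(
    step: int, base_lr: float, cycle_len: int = 50, t_mult: int = 2,
    min_lr_frac: float = 0.05, warmup: int = 0,
) -> float:
    """Learning rate at ``step`` under cosine annealing with warm restarts.

    ``warmup`` linearly ramps the rate over the first steps, which lets
    the Adam second-moment estimates stabilise before full-size updates.
    """
    length = cycle_len
    s = step
    while s >= length:
        s -= length
        length *= t_mult
    frac = s / max(length, 1)
    lo = base_lr * min_lr_frac
    out = lo + 0.5 * (base_lr - lo) * (1 + np.cos(np.pi * frac))
    if warmup > 0:
        out *= min(1.0, (step + 1) / warmup)
    return out
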