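"""AdamW with decoupled weight decay and a cosine-annealing schedule."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .tensor import Tensor


class AdamW:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params: List[Tensor] = list(params)
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

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )


class CosineSchedule:
    """lr(t) = lr_min + 0.5*(lr0 - lr_min)*(1 + cos(pi * t / t_max))."""

    def __init__(self, lr0: float, t_max: int, lr_min: float = 1e-6):
        self.lr0, self.t_max, self.lr_min = lr0, max(t_max, 1), lr_min

    def lr_at(self, t: int) -> float:
        t = min(t, self.t_max)
        return self.lr_min + 0.5 * (self.lr0 - self.lr_min) * (
            1.0 + np.cos(np.pi * t / self.t_max)
        )

    def apply(self, opt: AdamW, epoch: int) -> float:
        lr = float(self.lr_at(epoch))
        opt.lr = lr
        return lr
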