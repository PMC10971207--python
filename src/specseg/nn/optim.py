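"""Adam optimizer and step learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam", "StepLR"]


class Adam:
    """Adam with L2 weight decay added to the gradient (coupled form)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class StepLR:
    """lr(epoch) = base_lr * gamma ** floor(epoch / step_size)."""

    def __init__(self, optimizer: Adam, step_size: int, gamma: float, base_lr: float | None = None):
        self.opt = optimizer
        self.step_size = int(step_size)
        self.gamma = float(gamma)
        self.base_lr = float(base_lr if base_lr is not None else optimizer.lr)

    def lr_at(self, epoch: int) -> float:
        return self.base_lr * self.gamma ** (epoch // self.step_size)

    def set_epoch(self, epoch: int) -> float:
        self.opt.lr = self.lr_at(epoch)
        return self.opt.lr
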