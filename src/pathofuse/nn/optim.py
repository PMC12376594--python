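"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "WarmupCosineSchedule", "bce_with_logits"]


class AdamW:
    """Adaptive-moment optimiser with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
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
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class WarmupCosineSchedule:
    """Linear warm-up for `warmup_epochs`, then cosine annealing over `t_max`.

    Returns a multiplier applied to the optimiser's base learning rate at the
    start of each epoch; past warmup + t_max the multiplier stays at the
    cosine floor.
    """

    def __init__(self, base_lr: float, warmup_epochs: int, t_max: int,
                 min_lr_fraction: float = 0.0):
        self.base_lr = base_lr
        self.warmup_epochs = warmup_epochs
        self.t_max = max(t_max, 1)
        self.min_lr_fraction = min_lr_fraction

    def lr_at(self, epoch: int) -> float:
        if self.warmup_epochs > 0 and epoch < self.warmup_epochs:
            return self.base_lr * (epoch + 1) / self.warmup_epochs
        t = min(epoch - self.warmup_epochs, self.t_max)
        cos = 0.5 * (1.0 + np.cos(np.pi * t / self.t_max))
        lo = self.base_lr * self.min_lr_fraction
        return lo + (self.base_lr - lo) * cos

    def apply(self, optimizer: AdamW, epoch: int) -> float:
        lr = self.lr_at(epoch)
        optimizer.lr = lr
        return lr


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits: softplus(z) - z*y."""
    y = Tensor(np.asarray(targets, dtype=np.float64))
    return (logits.softplus() - logits * y).mean()
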