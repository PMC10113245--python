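"""Adam optimizer and a cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np


class Adam:
    """Adam with decoupled state per parameter.

    beta1 is the first-moment ("momentum") coefficient; the training recipe
    here uses beta1=0.9, beta2=0.999, eps=1e-8.
    """

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(epoch: int, total_epochs: int, lr_max: float = 1e-4,
              lr_min: float = 1e-5) -> float:
    """Cosine annealing from lr_max (epoch 0) to lr_min (last epoch)."""
    if total_epochs <= 1:
        return lr_max
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + math.cos(math.pi * t))
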