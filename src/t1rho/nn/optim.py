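"""First-order optimizers over :class:`~t1rho.nn.layers.Param` lists.

Weight decay is classic L2 regularization added to the gradient (the
convention of the reference deep-learning stacks at these recipes' vintage).
The learning rate is a mutable attribute so a per-epoch exponential schedule
``lr(e) = lr0 * decay**e`` can be applied by the training loop.
"""
from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam", "RMSProp"]


class _Optimizer:
    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.data
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.alpha = alpha
        self.eps = eps
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            g = p.grad + self.weight_decay * p.data
            v += (1 - self.alpha) * (g * g - v)
            p.data -= self.lr * g / (np.sqrt(v) + self.eps)
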