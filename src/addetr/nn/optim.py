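"""Optimizers for the numpy autodiff stack."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "SGD", "clip_grad_norm"]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    def __init__(self, params, lr=1e-2, momentum=0.0):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            if self.momentum:
                b *= self.momentum
                b += p.grad
                p.data -= self.lr * b
            else:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total
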