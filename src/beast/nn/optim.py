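"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "cosine_lr"]


def cosine_lr(step: int, total_steps: int, base_lr: float,
              min_lr: float = 0.0, warmup_steps: int = 0) -> float:
    """Cosine-annealed learning rate with optional linear warmup."""
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    progress = min(max(step - warmup_steps, 0) / span, 1.0)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + np.cos(np.pi * progress))


class AdamW:
    """AdamW with decoupled weight decay (default betas for masked-autoencoder
    recipes: (0.9, 0.95), weight decay 0.05)."""

    def __init__(self, params, lr: float = 1.5e-4, betas=(0.9, 0.95),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
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
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
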