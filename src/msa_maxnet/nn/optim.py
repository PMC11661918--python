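"""Optimizers. AdamW with decoupled weight decay is the one the trainer uses."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["AdamW"]


class AdamW:
    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params: list[Parameter] = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data *= (1 - self.lr * self.weight_decay)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        state = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            state[f"m{i}"] = m
            state[f"v{i}"] = v
        return state

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(state[f"m{i}"]).copy() for i in range(len(self.params))]
        self.v = [np.asarray(state[f"v{i}"]).copy() for i in range(len(self.params))]
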