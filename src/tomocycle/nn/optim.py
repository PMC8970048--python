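"""Optimizers. Wasserstein-style training uses RMSProp at a low learning rate
(default 5e-4), the standard recipe for weight-clipped critics."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["RMSProp"]


class RMSProp:
    """Root-mean-square propagation with per-parameter accumulators."""

    def __init__(self, layer: Layer, lr: float = 5e-4, rho: float = 0.99,
                 eps: float = 1e-8):
        self.layer = layer
        self.lr, self.rho, self.eps = lr, rho, eps
        self._state: dict[int, dict[str, np.ndarray]] = {}

    def step(self) -> None:
        for name, sub in self.layer.named_layers():
            if not sub.params:
                continue
            state = self._state.setdefault(
                id(sub), {k: np.zeros_like(v, dtype=np.float64) for k, v in sub.params.items()}
            )
            for k, p in sub.params.items():
                g = sub.grads[k].astype(np.float64)
                v = state[k]
                v *= self.rho
                v += (1.0 - self.rho) * g * g
                p -= (self.lr * g / (np.sqrt(v) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        self.layer.zero_grad()
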