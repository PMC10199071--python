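"""Adam optimizer with per-tensor norm clipping and element-wise value clipping.

Clipping is applied to the raw gradients before the Adam moment updates, norm
clip first, then value clip (the convention of the major frameworks' classic
optimizers).  The norm clip is per parameter tensor, not global.
"""

from __future__ import annotations

import numpy as np

from octlayers.nn.modules import Param

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        clipnorm: float | None = None,
        clipvalue: float | None = None,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clipnorm, self.clipvalue = clipnorm, clipvalue
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.clipnorm is not None:
                norm = float(np.sqrt((g * g).sum()))
                if norm > self.clipnorm:
                    g = g * (self.clipnorm / norm)
            if self.clipvalue is not None:
                g = np.clip(g, -self.clipvalue, self.clipvalue)
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
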