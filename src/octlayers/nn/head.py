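"""Batched, backprop-capable layer head stage.

Same mathematics as :mod:`octlayers.layer_head` but on channels-last
(B, H, W, N) batches and with an analytic backward pass: the clip stage passes
gradient where the cumulative map is below 1, the channel cumulative sum
back-propagates as a reversed cumulative sum, and the non-negativity stage as
a ReLU (or sigmoid-derivative) mask.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from octlayers.nn.modules import Module

__all__ = ["LayerHeadStage"]


class LayerHeadStage(Module):
    """(B, H, W, N) channel maps -> (B, W, N) ordered, bounded heights.

    ``cumulative=False`` removes the channel cumulative sum (the no-layer-order
    ablation): heights stay bounded by H but are no longer guaranteed ordered.
    ``nonnegativity`` selects the hard clamp ("relu", default) or a smooth
    sigmoid squashing of the raw maps onto (0, 1).
    """

    def __init__(self, cumulative: bool = True, nonnegativity: str = "relu"):
        if nonnegativity not in ("relu", "sigmoid"):
            raise ValueError("nonnegativity must be 'relu' or 'sigmoid'")
        self.cumulative = cumulative
        self.nonnegativity = nonnegativity

    def forward(self, x, training=False):
        if self.nonnegativity == "relu":
            a = np.maximum(x, 0.0)
            self._nonneg_grad = (x > 0).astype(x.dtype)
        else:
            a = expit(x)
            self._nonneg_grad = a * (1.0 - a)
        c = np.cumsum(a, axis=3) if self.cumulative else a
        self._clip_mask = (c < 1.0).astype(x.dtype)
        return np.minimum(c, 1.0).sum(axis=1)

    def backward(self, grad):
        # broadcast the per-column gradient over rows, then undo clip/cumsum/clamp
        gc = self._clip_mask * grad[:, None, :, :]
        if self.cumulative:
            ga = np.flip(np.cumsum(np.flip(gc, axis=3), axis=3), axis=3)
        else:
            ga = gc
        ga *= self._nonneg_grad
        return ga
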