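"""Layers and blocks with explicit forward/backward passes.

Feature maps are channels-last (B, H, W, C) internally: im2col patch rows are
then C-contiguous and convolution outputs need no transposition, which matters
on CPU.  The model facade accepts the conventional (B, 1, H, W) input.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Dropout",
    "SpatialDropout",
    "Swish",
    "DilationBlock",
    "AttentionBlock",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Module:
    """Base class: ``forward(x, training)`` then ``backward(grad)``.

    ``backward`` accumulates parameter gradients and returns the gradient with
    respect to the module input.  Caches from the last forward pass live on
    the instance; call forward before backward.
    """

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Swish(Module):
    """x * sigmoid(x); derivative s + y * (1 - s) with y = x * sigmoid(x)."""

    def forward(self, x, training=False):
        self._s = expit(x)
        self._y = x * self._s
        return self._y

    def backward(self, grad):
        d = self._y * (1.0 - self._s)
        d += self._s
        return grad * d


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, k*k*C) patch matrix, stride 1, same zero padding."""
    b, h, w, c = x.shape
    if k == 1:
        return x.reshape(b * h * w, c)
    p = dilation * (k - 1) // 2
    xp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
    xp[:, p:p + h, p:p + w, :] = x
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, h, w, k, k, c),
        strides=(s[0], s[1], s[2], s[1] * dilation, s[2] * dilation, s[3]),
    )
    return view.reshape(b * h * w, k * k * c)


class Conv2d(Module):
    """Stride-1 "same" 2D convolution with square kernel and dilation.

    The kernel is stored as a (k*k*cin, cout) matrix in (ky, kx, cin) patch
    order.  Glorot-uniform initialization (fan_in = cin*k*k, fan_out =
    cout*k*k); biases start at zero.  ``input_grad=False`` skips the input
    gradient (for a network's first layer).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        dilation: int = 1,
        *,
        bias: bool = True,
        input_grad: bool = True,
        rng: np.random.Generator,
        dtype=np.float32,
        name: str = "conv",
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for symmetric same padding")
        self.cin, self.cout, self.k, self.dilation = in_channels, out_channels, kernel_size, dilation
        fan_in = in_channels * kernel_size * kernel_size
        fan_out = out_channels * kernel_size * kernel_size
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, out_channels)).astype(dtype)
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(out_channels, dtype=dtype), f"{name}.b") if bias else None
        self.input_grad = input_grad

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def forward(self, x, training=False):
        b, h, w, c = x.shape
        self._shape = (b, h, w, c)
        self._col = _im2col(x, self.k, self.dilation)
        y = self._col @ self.W.value
        if self.b is not None:
            y += self.b.value
        return y.reshape(b, h, w, self.cout)

    def backward(self, grad):
        b, h, w, c = self._shape
        g2 = grad.reshape(b * h * w, self.cout)
        self.W.grad += self._col.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        self._col = None  # free the patch cache
        if not self.input_grad:
            return None
        if self.k == 1:
            return (g2 @ self.W.value.T).reshape(b, h, w, c)
        # input gradient = same-padded dilated convolution of grad with the
        # spatially flipped kernel, input/output channels swapped
        wk = self.W.value.reshape(self.k, self.k, c, self.cout)
        wk = wk[::-1, ::-1].transpose(0, 1, 3, 2)
        w2 = np.ascontiguousarray(wk).reshape(self.k * self.k * self.cout, c)
        return (_im2col(grad, self.k, self.dilation) @ w2).reshape(b, h, w, c)


class BatchNorm2d(Module):
    """Per-channel batch normalization with train/eval moving-average semantics."""

    def __init__(self, channels: int, *, momentum: float = 0.99, eps: float = 1e-3,
                 dtype=np.float32, name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1.0 - self.momentum) * mean).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1.0 - self.momentum) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        gscale = self.gamma.value * self._inv_std
        if not self._training:
            return grad * gscale
        gmean = grad.mean(axis=(0, 1, 2))
        gxhat_mean = (grad * xhat).mean(axis=(0, 1, 2))
        return gscale * (grad - gmean - xhat * gxhat_mean)


class Dropout(Module):
    """Inverted per-element dropout; identity in eval mode."""

    def __init__(self, rate: float, *, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(x.dtype)
        self._mask /= keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class SpatialDropout(Module):
    """Drops whole feature maps (per sample, per channel); identity in eval mode."""

    def __init__(self, rate: float, *, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        b, c = x.shape[0], x.shape[3]
        self._mask = (self.rng.random((b, 1, 1, c)) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class DilationBlock(Module):
    """Residual dilated-convolution block DB(filters, d1, d2).

    1x1 entry convolution -> spatial dropout -> three dilated 3x3 convolutions
    with dilations (d1, d2, d1) -> 1x1 exit convolution; the learned residual
    is added to the block input and the sum batch-normalized.  Spatial size is
    preserved throughout.  Swish follows the entry and the dilated
    convolutions; the exit 1x1 stays linear so the residual branch ends
    linearly before the addition.

    ``shortcut=False`` replaces the addition by a pass-through of the branch
    output (the no-shortcut ablation).
    """

    def __init__(self, width: int, filters: int, d1: int, d2: int, *,
                 dropout_rate: float = 0.1, shortcut: bool = True,
                 rng: np.random.Generator, dtype=np.float32, name: str = "db"):
        if d1 < 1 or d2 < 1:
            raise ValueError("dilation factors must be >= 1")
        self.shortcut = shortcut
        self.branch = Sequential(
            Conv2d(width, filters, 1, rng=rng, dtype=dtype, name=f"{name}.in"),
            Swish(),
            SpatialDropout(dropout_rate, rng=rng),
            Conv2d(filters, filters, 3, d1, rng=rng, dtype=dtype, name=f"{name}.c1"),
            Swish(),
            Conv2d(filters, filters, 3, d2, rng=rng, dtype=dtype, name=f"{name}.c2"),
            Swish(),
            Conv2d(filters, filters, 3, d1, rng=rng, dtype=dtype, name=f"{name}.c3"),
            Swish(),
            Conv2d(filters, width, 1, rng=rng, dtype=dtype, name=f"{name}.out"),
        )
        self.bn = BatchNorm2d(width, dtype=dtype, name=f"{name}.bn")

    def params(self):
        return self.branch.params() + self.bn.params()

    def forward(self, x, training=False):
        r = self.branch.forward(x, training)
        return self.bn.forward(x + r if self.shortcut else r, training)

    def backward(self, grad):
        gsum = self.bn.backward(grad)
        gbranch = self.branch.backward(gsum)
        return gbranch + gsum if self.shortcut else gbranch


class AttentionBlock(Module):
    """Gated self-attention: sigmoid gate times swish value, width preserved.

    Gate and value branches are *linear combinations* of the refined feature
    maps (bias-free 1x1 convolutions); per pixel, features are suppressed or
    emphasized based on the globally informed feature space.
    """

    def __init__(self, width: int, *, rng: np.random.Generator, dtype=np.float32,
                 name: str = "attn"):
        self.conv_gate = Conv2d(width, width, 1, bias=False, rng=rng, dtype=dtype,
                                name=f"{name}.gate")
        self.conv_value = Conv2d(width, width, 1, bias=False, rng=rng, dtype=dtype,
                                 name=f"{name}.value")
        self.act_value = Swish()

    def params(self):
        return self.conv_gate.params() + self.conv_value.params()

    def forward(self, x, training=False):
        self._gate = expit(self.conv_gate.forward(x, training))
        self._value = self.act_value.forward(self.conv_value.forward(x, training), training)
        return self._gate * self._value

    def backward(self, grad):
        gzg = grad * self._value * self._gate * (1.0 - self._gate)
        gzv = self.act_value.backward(grad * self._gate)
        return self.conv_gate.backward(gzg) + self.conv_value.backward(gzv)
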