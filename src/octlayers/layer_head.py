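"""The layer head: turn N 2D channel maps into N ordered per-column layer heights.

A layer height is the distance (in pixels, possibly fractional) from the top edge
of the B-scan to the layer, per A-scan (image column).  The head exploits a simple
observation: if a channel holds 1 at every pixel above a layer and 0 below it, the
layer height is the column-wise sum of that channel.  Ordering of multiple layers
is guaranteed by accumulating channels: with non-negative raw channels, the
cumulative sum along the channel axis is pixel-wise non-decreasing, so the column
sums (the heights) are non-decreasing in channel index — channel 0 is the
anatomically topmost layer.  Clipping the cumulative maps at 1 bounds every height
by the image height.

All four stages are differentiable almost everywhere, so the head can sit on top
of any fully convolutional backbone and be trained end-to-end against height
targets; no shortest-path or hole-filling post-processing is needed.

Functions here operate on plain ``(N, H, W)`` numpy arrays (channel, row, column).
The batched, backprop-capable version used during training lives in
:mod:`octlayers.nn.head`, built from the same primitives.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "enforce_nonnegative",
    "cumulative_channel_sum",
    "clip_unit",
    "column_sum_heights",
    "layer_head",
    "encode_heights",
]


def enforce_nonnegative(raw: np.ndarray) -> np.ndarray:
    """Element-wise ``max(x, 0)`` (ReLU).  Total on any real input."""
    return np.maximum(raw, 0.0)


def cumulative_channel_sum(maps: np.ndarray) -> np.ndarray:
    """Cumulative sum along the channel (first) axis.

    For non-negative input the output is pixel-wise non-decreasing in channel
    index, which is what guarantees the layer order downstream.
    """
    return np.cumsum(maps, axis=0)


def clip_unit(maps: np.ndarray) -> np.ndarray:
    """Element-wise ``min(x, 1)``.

    Applied after the cumulative sum; bounds column sums (heights) by the image
    height.  ``min`` is monotone, so channel monotonicity of the input survives.
    """
    return np.minimum(maps, 1.0)


def column_sum_heights(maps: np.ndarray) -> np.ndarray:
    """Sum each channel over rows: ``(N, H, W) -> (N, W)`` heights in ``[0, H]``."""
    return maps.sum(axis=1)


def layer_head(raw: np.ndarray) -> np.ndarray:
    """Full head: non-negativity -> channel cumsum -> clip at 1 -> column sums.

    Parameters
    ----------
    raw
        Any real ``(N, H, W)`` array.

    Returns
    -------
    ``(N, W)`` heights satisfying, for every input,
    ``0 <= h[k, x] <= H`` and ``h[k, x] <= h[k+1, x]``.
    """
    if raw.ndim != 3:
        raise ValueError(f"expected (N, H, W) maps, got shape {raw.shape}")
    return column_sum_heights(clip_unit(cumulative_channel_sum(enforce_nonnegative(raw))))


def encode_heights(heights: np.ndarray, H: int) -> np.ndarray:
    """Inverse of :func:`layer_head` on ordered, in-range height profiles.

    Builds raw ``(N, H, W)`` maps such that ``layer_head(encode_heights(h, H))``
    reproduces ``h`` exactly (up to float round-off).  In cumulative space,
    channel ``k`` at column ``x`` holds 1 in rows ``0 .. floor(h)-1``, the
    fractional part of ``h`` in row ``floor(h)`` and 0 below; the raw channels
    are the successive differences of the cumulative stack, which are
    non-negative precisely because the profile is ordered.

    Raises
    ------
    ValueError
        If the profile is unordered or outside ``[0, H]``.
    """
    heights = np.asarray(heights, dtype=float)
    if heights.ndim != 2:
        raise ValueError(f"expected (N, W) heights, got shape {heights.shape}")
    if np.any(heights < 0) or np.any(heights > H):
        raise ValueError("heights must lie in [0, H]")
    if np.any(np.diff(heights, axis=0) < 0):
        raise ValueError("heights must be non-decreasing in channel index")
    n, w = heights.shape
    rows = np.arange(H, dtype=float)[None, :, None]          # (1, H, 1)
    h = heights[:, None, :]                                  # (N, 1, W)
    # cumulative-space map: clip(h - row, 0, 1) gives 1 above, frac at floor(h), 0 below
    cumulative = np.clip(h - rows, 0.0, 1.0)                 # (N, H, W)
    raw = np.empty_like(cumulative)
    raw[0] = cumulative[0]
    raw[1:] = np.diff(cumulative, axis=0)
    return raw
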