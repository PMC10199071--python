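"""Drusen quantification from per-A-scan RPE and BM heights.

Drusen are deposits between the retinal pigment epithelium (RPE) and Bruch's
membrane (BM) and show up in OCT as a local elevation of the RPE above its
healthy position relative to BM.  The pipeline:

1. **Rectify** — subtract the RPE height from the BM height per A-scan.  This
   flattens retinal curvature and any rigid vertical offset, so no polynomial
   fit to the RPE is needed.
2. **Healthy offset** — the healthy RPE sits at a near-constant distance ``d``
   above BM, varying with physiology and image resolution.  ``d`` is estimated
   per volume as the mean elevation within the mode of the elevation histogram
   and its two directly neighboring bins.
3. **Voxelize** — per A-scan, drusen occupy the rows between the (elevated)
   RPE and the healthy RPE position ``bm - d``.
4. **Filter** — connected components of the en-face projection (B-scan index x
   A-scan index) whose maximum column height is below 2 px are removed as
   false positives; components reaching 2 px are kept whole, including their
   1-px fringes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "ElevationProfile",
    "HealthyRpeOffset",
    "DrusenVolumeMask",
    "rectify",
    "estimate_healthy_offset",
    "drusen_height_profile",
    "drusen_mask_bscan",
    "enface_projection",
    "filter_by_component_height",
    "drusen_volume",
    "quantify_drusen",
    "DrusenResult",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (heights are non-negative, so = floor(x + 0.5))."""
    return np.floor(x + 0.5).astype(int)


@dataclass
class ElevationProfile:
    """Per-A-scan RPE elevation above its healthy course: e(x) = bm(x) - rpe(x).

    ``e`` is >= 0 wherever valid (RPE above BM in image coordinates means a
    smaller row index, hence a positive difference); negative raw differences
    are logged and clamped to 0.  ``valid`` marks A-scans where both layers
    were annotated/predicted.
    """

    e: np.ndarray
    valid: np.ndarray


@dataclass
class HealthyRpeOffset:
    """Volume-wide healthy RPE-to-BM distance estimate with its histogram."""

    d: float
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin: int


@dataclass
class DrusenVolumeMask:
    """D x H x W boolean drusen voxels plus voxel spacing in micrometers."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None  # (axial, lateral, inter-B-scan)

    @property
    def enface(self) -> np.ndarray:
        """D x W per-position drusen column heights (voxel counts per A-scan)."""
        return self.voxels.sum(axis=1)


def rectify(rpe: np.ndarray, bm: np.ndarray) -> ElevationProfile:
    """Elevation e(x) = bm(x) - rpe(x) per A-scan; NaN in either layer -> invalid.

    Works on (W,) single B-scans or (D, W) whole volumes.  Being a per-column
    difference, the result is invariant to any rigid vertical shift applied to
    both layers — the rectification is what makes a polynomial "healthy RPE"
    fit unnecessary.
    """
    rpe = np.asarray(rpe, dtype=float)
    bm = np.asarray(bm, dtype=float)
    if rpe.shape != bm.shape:
        raise ValueError(f"layer grids differ: rpe {rpe.shape} vs bm {bm.shape}")
    valid = ~(np.isnan(rpe) | np.isnan(bm))
    e = np.where(valid, bm - rpe, 0.0)
    negative = valid & (e < 0)
    if np.any(negative):
        log.warning("clamping %d A-scans with RPE below BM to elevation 0",
                    int(negative.sum()))
        e = np.where(negative, 0.0, e)
    return ElevationProfile(e=e, valid=valid)


def estimate_healthy_offset(elevations: ElevationProfile, bin_width: float = 1.0) -> HealthyRpeOffset:
    """Histogram-mode estimate of the healthy RPE-to-BM offset.

    A histogram of all valid elevations at ``bin_width`` is taken; the estimate
    is the mean of the elevations falling in the modal bin or its two directly
    neighboring bins.  Ties between equally tall bins resolve to the
    smallest-elevation bin (the healthy baseline).  Annotations are typically
    pixel-quantized, hence the 1 px default bin width.
    """
    vals = elevations.e[elevations.valid]
    if vals.size == 0:
        raise ValueError("no valid A-scans to estimate the healthy offset from")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.floor(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    mode = int(np.argmax(counts))  # argmax takes the first = smallest-elevation bin
    idx = np.minimum(((vals - edges[0]) / bin_width).astype(int), len(counts) - 1)
    sel = np.abs(idx - mode) <= 1
    return HealthyRpeOffset(d=float(vals[sel].mean()), bin_edges=edges,
                            counts=counts, mode_bin=mode)


def drusen_height_profile(elevations: ElevationProfile, offset: HealthyRpeOffset | float) -> np.ndarray:
    """Per-A-scan drusen height: max(0, e(x) - d); invalid A-scans give 0."""
    d = offset.d if isinstance(offset, HealthyRpeOffset) else float(offset)
    h = np.maximum(0.0, elevations.e - d)
    return np.where(elevations.valid, h, 0.0)


def drusen_mask_bscan(
    rpe: np.ndarray,
    bm: np.ndarray,
    offset: HealthyRpeOffset | float,
    height: int,
) -> np.ndarray:
    """Voxelize drusen in one B-scan: rows between the RPE and the healthy RPE line.

    For every A-scan with positive drusen height, rows ``round(rpe) ..
    round(bm - d) - 1`` (0-based, row 0 at the image top, round half away from
    zero) are marked.  The column sums of the mask agree with the continuous
    drusen heights to within +/- 1 px of rounding.

    ``offset`` may also be a per-A-scan array (used by the legacy
    polynomial-baseline mode).
    """
    if isinstance(offset, HealthyRpeOffset):
        d = offset.d
    else:
        d = np.asarray(offset, dtype=float)
        d = float(d) if d.ndim == 0 else d
    elev = rectify(rpe, bm)
    h_dru = drusen_height_profile(elev, 0.0) - d  # e - d, invalid already zeroed
    h_dru = np.maximum(h_dru, 0.0) * elev.valid
    w = h_dru.shape[-1]
    mask = np.zeros((height, w), dtype=bool)
    cols = np.nonzero(h_dru > 0)[-1]
    if cols.size == 0:
        return mask
    d_cols = d if np.isscalar(d) else np.asarray(d)[..., cols]
    top = np.clip(_round_half_away(np.asarray(rpe, dtype=float)[..., cols]), 0, height)
    bot = np.clip(_round_half_away(np.asarray(bm, dtype=float)[..., cols] - d_cols), 0, height)
    rows = np.arange(height)[:, None]
    mask[:, cols] = (rows >= top[None, :]) & (rows < bot[None, :])
    return mask


def enface_projection(masks: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Stack per-B-scan masks and sum over rows: -> D x W en-face heights."""
    if isinstance(masks, list):
        widths = {m.shape[1] for m in masks}
        if len(widths) > 1:
            raise ValueError(f"inconsistent B-scan widths: {sorted(widths)}")
        masks = np.stack(masks)
    return masks.sum(axis=1)


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def filter_by_component_height(
    mask: DrusenVolumeMask,
    min_height: int = 2,
    connectivity: int = 8,
) -> DrusenVolumeMask:
    """Remove en-face connected components whose maximum height is below ``min_height``.

    The criterion is component-level and strict: a component peaking at
    ``min_height - 1`` px is deleted entirely; one reaching ``min_height`` is
    kept whole, including its 1-px-high fringe A-scans.  Default connectivity
    is 8 (diagonally touching drusen merge); 4 is available.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    enface = mask.voxels.sum(axis=1)
    labels, n = ndimage.label(enface > 0, structure=_STRUCTURES[connectivity])
    if n == 0:
        return DrusenVolumeMask(mask.voxels.copy(), mask.spacing)
    peak = ndimage.maximum(enface, labels=labels, index=np.arange(1, n + 1))
    bad = np.isin(labels, np.nonzero(np.atleast_1d(peak) < min_height)[0] + 1)
    voxels = mask.voxels & ~bad[:, None, :]
    return DrusenVolumeMask(voxels, mask.spacing)


def drusen_volume(mask: DrusenVolumeMask) -> tuple[float | None, int]:
    """(volume in cubic micrometers, voxel count); volume is None without spacing."""
    count = int(mask.voxels.sum())
    if mask.spacing is None:
        warnings.warn("no voxel spacing set; returning voxel count only", stacklevel=2)
        return None, count
    axial, lateral, inter = mask.spacing
    return count * axial * lateral * inter, count


@dataclass
class DrusenResult:
    mask: DrusenVolumeMask
    offset: HealthyRpeOffset
    volume_um3: float | None
    voxel_count: int

    @property
    def enface(self) -> np.ndarray:
        return self.mask.enface


def quantify_drusen(
    rpe: np.ndarray,
    bm: np.ndarray,
    height: int,
    spacing: tuple[float, float, float] | None = None,
    bin_width: float = 1.0,
    min_height: int = 2,
    connectivity: int = 8,
    legacy_polynomial_fit: bool = False,
) -> DrusenResult:
    """End-to-end drusen quantification for a volume of (D, W) layer heights.

    Deterministic composition: rectify -> volume-wide healthy-offset estimate ->
    per-B-scan voxel masks -> en-face projection -> component-height filter ->
    volume.

    ``legacy_polynomial_fit`` replaces the constant healthy offset with a
    per-B-scan 3rd-degree polynomial fit of the rectified elevation as the
    healthy baseline.  This mirrors an older pipeline for comparison only;
    after rectification the fit is unnecessary and can be detrimental, so it
    is off by default.
    """
    rpe = np.atleast_2d(np.asarray(rpe, dtype=float))
    bm = np.atleast_2d(np.asarray(bm, dtype=float))
    elev = rectify(rpe, bm)
    offset = estimate_healthy_offset(elev, bin_width=bin_width)
    if legacy_polynomial_fit:
        baseline = _legacy_polyfit_baseline(elev, fallback=offset.d)
        masks = np.stack([
            drusen_mask_bscan(rpe[b], bm[b], baseline[b], height)
            for b in range(rpe.shape[0])
        ])
    else:
        d = offset.d
        masks = np.stack([
            drusen_mask_bscan(rpe[b], bm[b], d, height) for b in range(rpe.shape[0])
        ])
    filtered = filter_by_component_height(
        DrusenVolumeMask(masks, spacing), min_height=min_height, connectivity=connectivity
    )
    if spacing is None:
        vol, count = None, int(filtered.voxels.sum())
    else:
        vol, count = drusen_volume(filtered)
    return DrusenResult(mask=filtered, offset=offset, volume_um3=vol, voxel_count=count)


def _legacy_polyfit_baseline(elev: ElevationProfile, fallback: float) -> np.ndarray:
    """Legacy: per-B-scan cubic fit of the rectified elevation as healthy baseline."""
    d, w = elev.e.shape
    x = np.arange(w, dtype=float)
    baseline = np.full((d, w), fallback)
    for b in range(d):
        v = elev.valid[b]
        if v.sum() < 4:
            continue
        coeffs = np.polyfit(x[v], elev.e[b, v], deg=3)
        baseline[b] = np.polyval(coeffs, x)
    return baseline
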