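"""Synthetic OCT B-scans and volumes with exactly known layer heights and drusen.

The generator emulates the geometry and appearance that matter for layer-height
regression and drusen quantification, with closed-form ground truth:

* **BM** follows a smooth curve (gentle tilt plus a low-frequency sinusoid) at a
  configurable vertical position with per-sample jitter.
* **RPE** runs at a constant healthy offset ``d`` above BM, locally elevated by
  drusen modeled as truncated Gaussian bumps (2D footprints over B-scan x
  A-scan position in volumes, so en-face components are realistic blobs).
* **EZ** runs at a constant offset ``g`` above the RPE.
* The image is a dark background plus one bright band per layer (Gaussian
  cross-section centered on the exact layer height), degraded by multiplicative
  speckle-like noise and additive Gaussian noise.

True heights are stored at full precision; the true drusen voxel mask is
derived with the same voxelization as the quantification pipeline, using the
true offset ``d`` — so discretization is the only disagreement source when the
pipeline runs on true heights.

What this does *not* emulate: real speckle statistics, vessel shadows, motion
artifacts, atrophy or fluid, or device-specific contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from octlayers.drusen import drusen_mask_bscan

__all__ = ["SyntheticConfig", "SyntheticSample", "generate_bscan", "generate_volume",
           "mask_annotations", "spectralis_preset"]

LAYER_NAMES = ("EZ", "RPE", "BM")  # top to bottom; channel 0 is topmost


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator.  Pixel units unless noted.

    Defaults target fast 128 x 128 experiments; :func:`spectralis_preset`
    scales the geometry to full-size 496 x 512 B-scans.
    """

    height: int = 128
    width: int = 128
    n_bscans: int = 16
    base_bm_row: float = 80.0           # mean BM height (distance from top)
    bm_tilt: float = 4.0                # max linear tilt across the width
    bm_curve_amplitude: float = 5.0
    bm_curve_cycles: float = 1.2        # sinusoid periods across the width
    rpe_offset: float = 10.0            # healthy RPE-to-BM distance d
    ez_offset: float = 8.0              # EZ-to-RPE distance g
    drusen_per_bscan: float = 1.5       # Poisson mean (per volume: per 8 B-scans of footprint)
    druse_amplitude: tuple[float, float] = (4.0, 16.0)
    druse_sigma_x: tuple[float, float] = (5.0, 14.0)
    druse_sigma_b: tuple[float, float] = (1.5, 4.0)   # footprint across B-scans
    druse_cutoff: float = 0.5           # bump truncated to 0 below this elevation
    band_intensity: tuple[float, float, float] = (0.8, 1.0, 0.6)  # EZ, RPE, BM
    band_sigma: tuple[float, float, float] = (1.2, 1.2, 1.2)
    background: float = 0.05
    speckle_sigma: float = 0.1          # multiplicative noise std; calibrated so
                                        # band argmax stays within 1 px of truth
    additive_sigma: float = 0.02
    vertical_jitter: float = 10.0       # uniform retina position jitter, px
    annotation_fraction: float = 1.0
    spacing: tuple[float, float, float] = (3.87, 11.3, 121.0)  # axial, lateral, inter-B-scan um

    def validate(self) -> None:
        if self.rpe_offset <= 0 or self.ez_offset <= 0:
            raise ValueError("layer offsets must be positive")
        if self.druse_amplitude[0] < 0:
            raise ValueError("druse amplitudes must be >= 0")


def spectralis_preset() -> SyntheticConfig:
    """Full-size geometry matching 496 x 512 B-scans."""
    return SyntheticConfig(
        height=496, width=512, base_bm_row=300.0, bm_tilt=15.0,
        bm_curve_amplitude=18.0, bm_curve_cycles=1.2, rpe_offset=14.0,
        ez_offset=12.0, druse_amplitude=(6.0, 40.0), druse_sigma_x=(10.0, 40.0),
        band_sigma=(2.5, 2.5, 2.5), vertical_jitter=40.0,
    )


@dataclass
class SyntheticSample:
    """Images with exact ground truth; B-scan samples have a leading axis of 1."""

    images: np.ndarray        # (D, H, W) float in [0, ~1]
    heights: np.ndarray       # (D, N, W) exact layer heights, px from top
    annotation: np.ndarray    # (D, N, W) bool, True = annotated
    drusen: np.ndarray        # (D, H, W) bool, true drusen voxels
    layer_names: tuple[str, ...]
    config: SyntheticConfig

    @property
    def image(self) -> np.ndarray:
        return self.images[0]


def _bm_curve(cfg: SyntheticConfig, rng: np.random.Generator, phase: float,
              tilt: float, jitter: float) -> np.ndarray:
    x = np.arange(cfg.width, dtype=float)
    u = x / max(cfg.width - 1, 1)
    return (cfg.base_bm_row + jitter + tilt * (u - 0.5)
            + cfg.bm_curve_amplitude * np.sin(2 * np.pi * cfg.bm_curve_cycles * u + phase))


def _render_bscan(cfg: SyntheticConfig, heights: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(cfg.height, dtype=float)[:, None]
    img = np.full((cfg.height, cfg.width), cfg.background)
    for k, (amp, sig) in enumerate(zip(cfg.band_intensity, cfg.band_sigma)):
        img += amp * np.exp(-0.5 * ((rows - heights[k][None, :]) / sig) ** 2)
    if cfg.speckle_sigma > 0:
        img *= np.maximum(1.0 + cfg.speckle_sigma * rng.standard_normal(img.shape), 0.0)
    if cfg.additive_sigma > 0:
        img += cfg.additive_sigma * rng.standard_normal(img.shape)
    return np.maximum(img, 0.0).astype(np.float32)


def _check_on_image(cfg: SyntheticConfig, heights: np.ndarray) -> None:
    margin = 3.0 * max(cfg.band_sigma)
    if heights.min() < margin or heights.max() > cfg.height - margin:
        raise ValueError(
            "configured geometry pushes layers off-image "
            f"(heights span [{heights.min():.1f}, {heights.max():.1f}] in a "
            f"{cfg.height}-px image; need a {margin:.1f}-px band margin)"
        )


def _drusen_bumps_1d(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    x = np.arange(cfg.width, dtype=float)
    bump = np.zeros(cfg.width)
    n = rng.poisson(cfg.drusen_per_bscan)
    for _ in range(n):
        x0 = rng.uniform(0.1 * cfg.width, 0.9 * cfg.width)
        a = rng.uniform(*cfg.druse_amplitude)
        sx = rng.uniform(*cfg.druse_sigma_x)
        bump += a * np.exp(-0.5 * ((x - x0) / sx) ** 2)
    return np.where(bump >= cfg.druse_cutoff, bump, 0.0)


def generate_bscan(cfg: SyntheticConfig, rng: np.random.Generator) -> SyntheticSample:
    """One synthetic B-scan; a pure function of (cfg, rng state)."""
    cfg.validate()
    bump = _drusen_bumps_1d(cfg, rng)
    phase = rng.uniform(0, 2 * np.pi)
    tilt = rng.uniform(-cfg.bm_tilt, cfg.bm_tilt)
    jitter = rng.uniform(-cfg.vertical_jitter, cfg.vertical_jitter)
    bm = _bm_curve(cfg, rng, phase, tilt, jitter)
    rpe = bm - cfg.rpe_offset - bump
    ez = rpe - cfg.ez_offset
    heights = np.stack([ez, rpe, bm])
    _check_on_image(cfg, heights)
    img = _render_bscan(cfg, heights, rng)
    drusen = drusen_mask_bscan(rpe, bm, cfg.rpe_offset, cfg.height)
    sample = SyntheticSample(
        images=img[None], heights=heights[None],
        annotation=np.ones((1, 3, cfg.width), dtype=bool),
        drusen=drusen[None], layer_names=LAYER_NAMES, config=cfg,
    )
    if cfg.annotation_fraction < 1.0:
        sample = mask_annotations(sample, cfg.annotation_fraction, rng)
    return sample


def generate_volume(cfg: SyntheticConfig, rng: np.random.Generator) -> SyntheticSample:
    """A D-B-scan volume with 3D drusen bumps (2D Gaussian en-face footprints)."""
    cfg.validate()
    d = cfg.n_bscans
    if d < 1:
        raise ValueError("n_bscans must be >= 1")
    x = np.arange(cfg.width, dtype=float)[None, :]
    b = np.arange(d, dtype=float)[:, None]
    bump = np.zeros((d, cfg.width))
    n_drusen = rng.poisson(cfg.drusen_per_bscan * d / 8.0)
    for _ in range(n_drusen):
        x0 = rng.uniform(0.1 * cfg.width, 0.9 * cfg.width)
        b0 = rng.uniform(0, d - 1) if d > 1 else 0.0
        a = rng.uniform(*cfg.druse_amplitude)
        sx = rng.uniform(*cfg.druse_sigma_x)
        sb = rng.uniform(*cfg.druse_sigma_b)
        bump += a * np.exp(-0.5 * (((x - x0) / sx) ** 2 + ((b - b0) / sb) ** 2))
    bump = np.where(bump >= cfg.druse_cutoff, bump, 0.0)

    phase = rng.uniform(0, 2 * np.pi)
    tilt = rng.uniform(-cfg.bm_tilt, cfg.bm_tilt)
    jitter = rng.uniform(-cfg.vertical_jitter, cfg.vertical_jitter)
    images, heights, drusen = [], [], []
    for i in range(d):
        # BM drifts slowly across the volume via a phase walk
        bm = _bm_curve(cfg, rng, phase + 0.2 * np.pi * i / max(d - 1, 1), tilt, jitter)
        rpe = bm - cfg.rpe_offset - bump[i]
        ez = rpe - cfg.ez_offset
        h = np.stack([ez, rpe, bm])
        _check_on_image(cfg, h)
        images.append(_render_bscan(cfg, h, rng))
        heights.append(h)
        drusen.append(drusen_mask_bscan(rpe, bm, cfg.rpe_offset, cfg.height))
    sample = SyntheticSample(
        images=np.stack(images), heights=np.stack(heights),
        annotation=np.ones((d, 3, cfg.width), dtype=bool),
        drusen=np.stack(drusen), layer_names=LAYER_NAMES, config=cfg,
    )
    if cfg.annotation_fraction < 1.0:
        sample = mask_annotations(sample, cfg.annotation_fraction, rng)
    return sample


def mask_annotations(sample: SyntheticSample, fraction: float,
                     rng: np.random.Generator | None = None) -> SyntheticSample:
    """Keep a centered contiguous fraction of A-scan annotations per layer.

    Emulates datasets annotated only in a central region around the fovea.
    The kept region is deterministic (centered); ``rng`` is accepted for
    signature symmetry with the generators but unused.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    w = sample.images.shape[-1]
    n_keep = int(w * fraction)
    start = (w - n_keep) // 2
    window = np.zeros_like(sample.annotation)
    window[..., start:start + n_keep] = True
    return replace(sample, annotation=sample.annotation & window)
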