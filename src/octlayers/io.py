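"""Readers/writers for the generic interchange formats and dataset preprocessing.

A volume on disk is a directory with:

* ``images.tiff``  — multi-page TIFF, one page per B-scan (row 0 = image top);
  alternatively a set of ``bscan_*.png`` files in lexical order.
* ``meta.json``    — ``{"spacing_um": [axial, lateral, inter_bscan], "device": ...,
  "volume_id": ...}``; spacing may be absent (volume computations degrade to
  voxel counts with a warning).
* ``heights.csv``  — optional long-format layer annotations with columns
  ``bscan_index, ascan_index, layer_name, height_px`` (0-based indices, '.'
  decimal separator, empty field = unannotated).

Proprietary device formats are not parsed natively; convert them to this
layout with any external reader.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from octlayers.backbone import HeightRegressionModel, load_checkpoint
from octlayers.training import normalize

log = logging.getLogger(__name__)

__all__ = ["VolumeBundle", "read_volume", "write_volume",
           "crop_and_filter_annotations", "predict",
           "heights_to_frame", "frame_to_heights"]


@dataclass
class VolumeBundle:
    images: np.ndarray                                  # (D, H, W)
    spacing: tuple[float, float, float] | None = None   # um: axial, lateral, inter-B-scan
    device: str | None = None
    volume_id: str | None = None
    heights: np.ndarray | None = None                   # (D, N, W), NaN = unannotated
    layer_names: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.images.ndim != 3:
            raise ValueError(f"images must be (D, H, W), got {self.images.shape}")
        if self.heights is not None:
            d, _, w = self.images.shape
            if self.heights.ndim != 3 or self.heights.shape[0] != d or self.heights.shape[2] != w:
                raise ValueError(
                    f"heights {self.heights.shape} inconsistent with images {self.images.shape}"
                )


def heights_to_frame(heights: np.ndarray, layer_names: tuple[str, ...]) -> pd.DataFrame:
    """(D, N, W) heights -> long-format DataFrame; NaN rows are kept as empty."""
    d, n, w = heights.shape
    b, k, x = np.meshgrid(np.arange(d), np.arange(n), np.arange(w), indexing="ij")
    return pd.DataFrame({
        "bscan_index": b.ravel(),
        "ascan_index": x.ravel(),
        "layer_name": np.array(layer_names)[k.ravel()],
        "height_px": heights.ravel(),
    })


def frame_to_heights(df: pd.DataFrame, d: int, w: int,
                     layer_names: tuple[str, ...] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Long-format DataFrame -> (D, N, W) heights (NaN where absent)."""
    if layer_names is None:
        layer_names = tuple(dict.fromkeys(df["layer_name"]))
    index = {name: k for k, name in enumerate(layer_names)}
    heights = np.full((d, len(layer_names), w), np.nan)
    bi = df["bscan_index"].to_numpy(dtype=int)
    xi = df["ascan_index"].to_numpy(dtype=int)
    if bi.size and (bi.max() >= d or xi.max() >= w):
        bad = int(bi[(bi >= d) | (xi >= w)][0]) if (bi >= d).any() else int(bi[xi >= w][0])
        raise ValueError(f"heights CSV indexes B-scan/A-scan outside the volume "
                         f"(offending B-scan {bad}; volume is D={d}, W={w})")
    ki = np.array([index[name] for name in df["layer_name"]])
    heights[bi, ki, xi] = df["height_px"].to_numpy(dtype=float)
    return heights, layer_names


def write_volume(bundle: VolumeBundle, path: str | Path) -> None:
    """Write the bundle losslessly (images, metadata, optional heights)."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "images.tiff", bundle.images, photometric="minisblack")
    meta: dict = {"device": bundle.device, "volume_id": bundle.volume_id}
    if bundle.spacing is not None:
        meta["spacing_um"] = list(bundle.spacing)
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if bundle.heights is not None:
        names = bundle.layer_names or tuple(f"layer{k}" for k in range(bundle.heights.shape[1]))
        heights_to_frame(bundle.heights, names).to_csv(path / "heights.csv", index=False)


def _read_images(path: Path) -> np.ndarray:
    tiff = path / "images.tiff"
    if tiff.exists():
        images = tifffile.imread(tiff)
        return images[None] if images.ndim == 2 else images
    pngs = sorted(path.glob("bscan_*.png"))
    if pngs:
        from PIL import Image
        return np.stack([np.asarray(Image.open(p)) for p in pngs])
    raise FileNotFoundError(f"no images.tiff or bscan_*.png in {path}")


def read_volume(path: str | Path) -> VolumeBundle:
    """Read a volume directory; errors on missing metadata or dimension mismatch."""
    path = Path(path)
    images = _read_images(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    spacing = meta.get("spacing_um")
    if spacing is None:
        log.warning("no voxel spacing in %s; volume computations degrade to voxel counts",
                    meta_path)
    heights = layer_names = None
    csv_path = path / "heights.csv"
    if csv_path.exists():
        df = pd.read_csv(csv_path, float_precision="round_trip")
        heights, layer_names = frame_to_heights(df, images.shape[0], images.shape[2])
    bundle = VolumeBundle(
        images=images,
        spacing=tuple(spacing) if spacing is not None else None,
        device=meta.get("device"),
        volume_id=meta.get("volume_id"),
        heights=heights,
        layer_names=layer_names,
    )
    bundle.validate()
    return bundle


def crop_and_filter_annotations(
    bundle: VolumeBundle,
    center_width: int = 512,
    min_annotated: int = 256,
) -> tuple[VolumeBundle, dict]:
    """Keep the central ``center_width`` A-scans; drop B-scans lacking annotations.

    A B-scan survives only if *every* layer has strictly more than
    ``min_annotated`` annotated A-scans after the crop (a B-scan with exactly
    ``min_annotated`` in some layer is dropped).  Returns the new bundle and a
    report with kept/dropped B-scan indices.
    """
    if bundle.heights is None:
        raise ValueError("bundle has no height annotations to filter on")
    d, _, w = bundle.images.shape
    if center_width > w:
        raise ValueError(f"center_width {center_width} exceeds volume width {w}")
    start = (w - center_width) // 2
    sl = slice(start, start + center_width)
    images = bundle.images[:, :, sl]
    heights = bundle.heights[:, :, sl]
    counts = (~np.isnan(heights)).sum(axis=2)          # (D, N)
    keep = (counts > min_annotated).all(axis=1)
    report = {
        "kept": np.nonzero(keep)[0].tolist(),
        "dropped": np.nonzero(~keep)[0].tolist(),
        "center_width": center_width,
        "min_annotated": min_annotated,
    }
    if not keep.any():
        warnings.warn("all B-scans dropped by the annotation filter", stacklevel=2)
    new = replace(bundle, images=images[keep], heights=heights[keep])
    new.validate()
    return new, report


def predict(
    model: HeightRegressionModel | str | Path,
    bundle: VolumeBundle,
) -> np.ndarray:
    """Per-B-scan layer heights (D, N, W) from a model or checkpoint path.

    Each B-scan is normalized to zero mean / unit variance and passed through
    the network in eval mode; the model is fully convolutional, so any H and W
    are accepted.  Deterministic.
    """
    if not isinstance(model, HeightRegressionModel):
        model = load_checkpoint(model)
    bundle.validate()
    out = []
    for img in bundle.images:
        x = normalize(np.asarray(img, dtype=np.float32))[None, None]
        out.append(model.forward(x, training=False)[0])
    return np.stack(out)
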