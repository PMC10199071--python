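"""End-to-end training of the height-regression model.

The loss is the *summed* squared error (SSE) over annotated (layer, A-scan)
pairs — deliberately not averaged, so sparsely annotated B-scans contribute
less than fully annotated ones.  The learning rate starts at 1e-3 and decays by
exp(-0.1) per epoch; optimization is Adam with per-tensor norm clipping at 1
and element-wise value clipping at 0.5.  Data is shuffled each epoch and
augmented on the fly with random horizontal flips and a vertical repositioning
that makes the retina's vertical position uniformly distributed: the B-scan is
first centered so the row ``center_offset_above_bm`` pixels above the mean BM
height lands mid-image, then shifted by a uniform integer draw.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from octlayers.backbone import HeightRegressionModel
from octlayers.nn.optim import Adam

log = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "TrainingSample",
    "sse_loss",
    "sse_loss_grad",
    "lr_schedule",
    "augment_horizontal_flip",
    "augment_vertical_position",
    "normalize",
    "train",
    "TrainResult",
]


@dataclass
class TrainingConfig:
    epochs: int = 35
    lr_initial: float = 1e-3
    lr_decay: float = 0.1               # lr(e) = lr_initial * exp(-lr_decay * e)
    batch_size: int = 2
    grad_clip_norm: float = 1.0
    grad_clip_value: float = 0.5
    center_offset_above_bm: float = 75.0   # px above mean BM that is centered
    vshift_range: int = 180                # uniform integer shift in [-v, v]
    hflip_prob: float = 0.5
    augment_vertical: bool = True
    bm_layer: int = -1                     # index of BM in the layer axis
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be > 0")
        if self.vshift_range < 0:
            raise ValueError("vshift_range must be >= 0")


@dataclass
class TrainingSample:
    """One B-scan with per-A-scan height targets; NaN-free, masked instead."""

    image: np.ndarray        # (H, W)
    heights: np.ndarray      # (N, W)
    annotation: np.ndarray   # (N, W) bool


def sse_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Summed squared height error over annotated entries (no averaging)."""
    if pred.shape != target.shape or pred.shape != mask.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target.shape}, "
                         f"mask {mask.shape}")
    diff = np.where(mask, pred - target, 0.0)
    return float((diff * diff).sum())


def sse_loss_grad(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """d(SSE)/d(pred): 2 * (pred - target) on annotated entries, 0 elsewhere."""
    return np.where(mask, 2.0 * (pred - target), 0.0)


def lr_schedule(epoch: int, cfg: TrainingConfig) -> float:
    """lr_initial * exp(-lr_decay * epoch); epoch 0 gives lr_initial."""
    return cfg.lr_initial * float(np.exp(-cfg.lr_decay * epoch))


def augment_horizontal_flip(sample: TrainingSample, rng: np.random.Generator,
                            prob: float = 0.5, *, force: bool | None = None) -> TrainingSample:
    """Mirror image columns and height columns together with probability ``prob``."""
    do_flip = force if force is not None else (rng.random() < prob)
    if not do_flip:
        return sample
    return TrainingSample(
        image=sample.image[:, ::-1].copy(),
        heights=sample.heights[:, ::-1].copy(),
        annotation=sample.annotation[:, ::-1].copy(),
    )


def augment_vertical_position(sample: TrainingSample, rng: np.random.Generator,
                              cfg: TrainingConfig, *, shift: int | None = None) -> TrainingSample:
    """Center the retina, then apply a random integer vertical shift.

    The mean BM height over annotated A-scans defines the reference: the row
    ``center_offset_above_bm`` px above it is moved to the image middle, then a
    uniform integer shift in [-vshift_range, vshift_range] is added (pass
    ``shift`` to force it).  Vacated rows are zero-filled; heights move rigidly
    with the image, and heights shifted outside [0, H] lose their annotation.
    """
    h_img = sample.image.shape[0]
    bm = sample.heights[cfg.bm_layer]
    bm_mask = sample.annotation[cfg.bm_layer]
    if not bm_mask.any():
        raise ValueError("vertical centering needs at least one annotated BM A-scan")
    mean_bm = float(bm[bm_mask].mean())
    reference_row = mean_bm - cfg.center_offset_above_bm
    center_shift = int(round(h_img / 2.0 - reference_row))
    u = shift if shift is not None else int(rng.integers(-cfg.vshift_range, cfg.vshift_range + 1))
    total = center_shift + u

    image = np.zeros_like(sample.image)
    if total >= 0:
        if total < h_img:
            image[total:] = sample.image[:h_img - total]
    else:
        if -total < h_img:
            image[:h_img + total] = sample.image[-total:]
    heights = sample.heights + total
    annotation = sample.annotation & (heights >= 0) & (heights <= h_img)
    return TrainingSample(image=image, heights=heights, annotation=annotation)


def normalize(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance per B-scan; constant images map to all zeros."""
    mean = image.mean()
    std = image.std()
    if std == 0:
        log.warning("constant image in normalization; returning zeros")
        return np.zeros_like(image, dtype=np.float32)
    return ((image - mean) / std).astype(np.float32)


@dataclass
class TrainResult:
    history: dict[str, list[float]]
    best_epoch: int | None
    best_val_sse: float | None
    best_state: dict[str, np.ndarray] | None


def _epoch_val_sse(model: HeightRegressionModel, samples: list[TrainingSample]) -> float:
    total = 0.0
    for s in samples:
        x = normalize(s.image)[None, None]
        pred = model.forward(x, training=False)[0]
        total += sse_loss(pred, s.heights, s.annotation)
    return total


def train(
    model: HeightRegressionModel,
    dataset: list[TrainingSample],
    cfg: TrainingConfig,
    val_dataset: list[TrainingSample] | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Train with shuffled mini-batches, on-the-fly augmentation, SSE + Adam.

    Deterministic for a fixed seed on CPU: the config seed drives shuffling,
    augmentation and nothing else (weight init is seeded at model build time).
    Restores the best-on-validation weights at the end when a validation set is
    given.  Aborts on non-finite loss.
    """
    cfg.validate()
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), clipnorm=cfg.grad_clip_norm, clipvalue=cfg.grad_clip_value)
    history: dict[str, list[float]] = {"epoch": [], "lr": [], "train_sse": [], "val_sse": []}
    best_epoch, best_val, best_state = None, np.inf, None

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = []
            for idx in order[start:start + cfg.batch_size]:
                s = dataset[idx]
                s = augment_horizontal_flip(s, rng, cfg.hflip_prob)
                if cfg.augment_vertical:
                    s = augment_vertical_position(s, rng, cfg)
                batch.append(s)
            x = np.stack([normalize(s.image) for s in batch])[:, None]
            target = np.stack([s.heights for s in batch]).astype(np.float32)
            mask = np.stack([s.annotation for s in batch])
            pred = model.forward(x, training=True)
            loss = sse_loss(pred, target, mask)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, batch starting {start}"
                )
            epoch_loss += loss
            model.backward(sse_loss_grad(pred, target, mask).astype(np.float32))
            opt.step()
            opt.zero_grad()
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_sse"].append(epoch_loss / len(dataset))
        if val_dataset:
            val = _epoch_val_sse(model, val_dataset) / len(val_dataset)
            history["val_sse"].append(val)
            if val < best_val:
                best_epoch, best_val = epoch, val
                best_state = copy.deepcopy(model.get_state())
        else:
            history["val_sse"].append(float("nan"))
        if verbose:
            log.info("epoch %d: lr=%.3e train_sse=%.2f val_sse=%s",
                     epoch, lr, history["train_sse"][-1], history["val_sse"][-1])
    if best_state is not None:
        model.set_state(best_state)
    return TrainResult(
        history=history,
        best_epoch=best_epoch,
        best_val_sse=None if not val_dataset else float(best_val),
        best_state=best_state,
    )
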