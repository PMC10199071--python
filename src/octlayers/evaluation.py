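"""Evaluation metrics: per-volume MAE with bootstrap CIs, Dice, volume agreement.

MAE follows rounded-prediction semantics by default: predicted heights are
rounded to integer pixels before the absolute difference (ground-truth
annotations are already pixel-quantized); pass ``round_predictions=False`` to
round the final MAE instead.  Reported means and standard deviations aggregate
the per-volume MAEs, and 95% confidence intervals come from resampling volumes
with replacement (10,000 resamples, each 80% of the dataset size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MaeReport", "mae_per_volume", "bootstrap_ci", "dice",
           "VolumeAgreement", "volume_agreement"]


@dataclass
class MaeReport:
    per_volume: np.ndarray          # (n_volumes, n_layers); NaN where undefined
    mean: np.ndarray                # (n_layers,)
    sd: np.ndarray                  # (n_layers,)
    layer_names: tuple[str, ...] | None = None
    ci95: list[tuple[float, float]] | None = None


def mae_per_volume(
    pred_volumes: list[np.ndarray],
    gt_volumes: list[np.ndarray],
    layer_names: tuple[str, ...] | None = None,
    round_predictions: bool = True,
) -> MaeReport:
    """Per-volume, per-layer mean absolute height error in pixels.

    Each volume is a (D, N, W) array; ground truth may be partial (NaN =
    unannotated).  A layer with zero annotated A-scans in a volume yields NaN
    for that cell, with a warning; means/SDs ignore NaNs.
    """
    if len(pred_volumes) != len(gt_volumes):
        raise ValueError("pred and gt volume lists differ in length")
    rows = []
    for v, (pred, gt) in enumerate(zip(pred_volumes, gt_volumes)):
        if pred.shape != gt.shape:
            raise ValueError(f"volume {v}: shape mismatch {pred.shape} vs {gt.shape}")
        p = np.round(pred) if round_predictions else pred
        err = np.abs(p - gt)                       # NaN where unannotated
        n_layers = pred.shape[1]
        row = np.full(n_layers, np.nan)
        for k in range(n_layers):
            vals = err[:, k, :]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                warnings.warn(f"volume {v}, layer {k}: no annotated A-scans",
                              stacklevel=2)
            else:
                row[k] = vals.mean()
        rows.append(row)
    per_volume = np.array(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_volume, axis=0)
        sd = np.nanstd(per_volume, axis=0, ddof=0)
    if not round_predictions:
        mean = np.round(mean)
    return MaeReport(per_volume=per_volume, mean=mean, sd=sd, layer_names=layer_names)


def bootstrap_ci(
    values: np.ndarray,
    n_resamples: int = 10_000,
    sample_frac: float = 0.8,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """95% bootstrap CI of the mean: resample with replacement, 80% of n per draw."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least 2 values for a bootstrap CI")
    rng = rng or np.random.default_rng()
    m = int(np.ceil(sample_frac * values.size))
    idx = rng.integers(0, values.size, size=(n_resamples, m))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice score 2|a n b| / (|a| + |b|); two empty masks agree perfectly (1.0).

    The empty/empty convention matters here because drusen-free B-scans are
    common and should count as agreement on absence.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class VolumeAgreement:
    pearson_r: float
    diffs_a: np.ndarray     # method A volume - reference, per volume
    diffs_b: np.ndarray
    n_a_closer: int         # volumes where |A - ref| < |B - ref| strictly


def volume_agreement(
    vols_a: np.ndarray,
    vols_b: np.ndarray,
    reference: np.ndarray | None = None,
) -> VolumeAgreement:
    """Pearson correlation between two methods' drusen volumes plus, given a
    reference (e.g. the mean of two human readers), signed per-volume
    differences and the count of volumes where method A is strictly closer."""
    a = np.asarray(vols_a, dtype=float)
    b = np.asarray(vols_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("volume lists must be 1-D and aligned")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance volumes")
    r = float(stats.pearsonr(a, b).statistic)
    if reference is None:
        return VolumeAgreement(r, a - a, b - b, 0)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != a.shape:
        raise ValueError("reference must align with the volume lists")
    da, db = a - ref, b - ref
    return VolumeAgreement(r, da, db, int((np.abs(da) < np.abs(db)).sum()))
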