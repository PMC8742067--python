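"""Segmentation and intake-accuracy evaluation.

Pixel metrics treat "food" as the positive class:

* global segmentation accuracy  GSA = (TP + TN) / total,
* food segmentation accuracy    FSA = TP / (TP + FN)  (recall on food),
* IOU = |target & prediction| / |target | prediction|, which unlike FSA
  penalises false positives.

Intake errors compare percent intake derived from the prediction against
percent intake derived from the ground truth, each relative to its own
full-portion reference plate; 2D uses segmented pixel counts, 3D uses
integrated volumes.  The sign convention is fixed throughout as
predicted minus target: a positive intake error means intake was
over-estimated (equivalently, the remaining food was under-estimated).

Summaries are mean +/- sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyImage,
    EmptyList,
    EmptyUnion,
    NoFoodInTarget,
    ShapeMismatch,
    ZeroReference,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MeanSD:
    mean: float
    sd: float

    def __str__(self) -> str:
        return f"{self.mean:.1f} ({self.sd:.1f})"


def confusion_counts(target: np.ndarray, prediction: np.ndarray) -> ConfusionCounts:
    """2-class pixel contingency with food as the positive class."""
    target = np.asarray(target, dtype=bool)
    prediction = np.asarray(prediction, dtype=bool)
    if target.shape != prediction.shape:
        raise ShapeMismatch(f"target {target.shape} vs prediction {prediction.shape}")
    tp = int(np.count_nonzero(target & prediction))
    tn = int(np.count_nonzero(~target & ~prediction))
    fp = int(np.count_nonzero(~target & prediction))
    fn = int(np.count_nonzero(target & ~prediction))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def global_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise EmptyImage("no pixels")
    return (c.tp + c.tn) / c.total


def food_segmentation_accuracy(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise NoFoodInTarget("target mask has no food pixels")
    return c.tp / (c.tp + c.fn)


def iou(target: np.ndarray, prediction: np.ndarray) -> float:
    target = np.asarray(target, dtype=bool)
    prediction = np.asarray(prediction, dtype=bool)
    if target.shape != prediction.shape:
        raise ShapeMismatch(f"target {target.shape} vs prediction {prediction.shape}")
    union = int(np.count_nonzero(target | prediction))
    if union == 0:
        raise EmptyUnion("both masks empty; IOU undefined")
    return int(np.count_nonzero(target & prediction)) / union


def _percent_intake(series: np.ndarray, reference: int) -> np.ndarray:
    ref = series[reference]
    if ref <= 0:
        raise ZeroReference("reference portion is zero")
    return 100.0 * (1.0 - series / ref)


def intake_error_2d(
    pred_mask_px: np.ndarray | list,
    gt_mask_px: np.ndarray | list,
    reference: int = 0,
) -> np.ndarray:
    """Per-plate 2D percent-intake error (predicted minus target).

    2D percent intake of plate k is 100 * (1 - px_k / px_reference), with
    the prediction and the ground truth each using their own reference
    pixel count; by construction the error at the reference plate is 0.
    """
    pred = np.asarray(pred_mask_px, dtype=float)
    gt = np.asarray(gt_mask_px, dtype=float)
    if pred.shape != gt.shape:
        raise ShapeMismatch("prediction and ground-truth series lengths differ")
    return _percent_intake(pred, reference) - _percent_intake(gt, reference)


def intake_error_3d(
    pred_vol_ml: np.ndarray | list,
    gt_vol_ml: np.ndarray | list,
    reference: int = 0,
) -> np.ndarray:
    """Per-plate 3D percent-intake error: as 2D but on integrated volumes."""
    pred = np.asarray(pred_vol_ml, dtype=float)
    gt = np.asarray(gt_vol_ml, dtype=float)
    if pred.shape != gt.shape:
        raise ShapeMismatch("prediction and ground-truth series lengths differ")
    return _percent_intake(pred, reference) - _percent_intake(gt, reference)


@dataclass(frozen=True)
class VolumeErrorStats:
    mean_absolute_error_ml: float
    mean_error_bias_ml: float
    volume_intake_error_ml: np.ndarray  # per plate

    def __iter__(self):
        yield self.mean_absolute_error_ml
        yield self.mean_error_bias_ml
        yield self.volume_intake_error_ml


def volume_error_stats(
    pred_vol_ml: np.ndarray | list,
    gt_vol_ml: np.ndarray | list,
    reference: int = 0,
) -> VolumeErrorStats:
    """Absolute error, signed bias and per-plate volume intake error (mL).

    Volume intake error subtracts intakes, so a constant per-plate offset
    present in both the reference and the current plate cancels.
    """
    pred = np.asarray(pred_vol_ml, dtype=float)
    gt = np.asarray(gt_vol_ml, dtype=float)
    if pred.shape != gt.shape:
        raise ShapeMismatch("prediction and ground-truth series lengths differ")
    err = pred - gt
    pred_intake = pred[reference] - pred
    gt_intake = gt[reference] - gt
    return VolumeErrorStats(
        mean_absolute_error_ml=float(np.mean(np.abs(err))),
        mean_error_bias_ml=float(np.mean(err)),
        volume_intake_error_ml=pred_intake - gt_intake,
    )


def summarize(values) -> MeanSD:
    """Mean +/- sample standard deviation; n=1 reports SD 0 with a warning."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyList("cannot summarize an empty list")
    if arr.size == 1:
        warnings.warn("summarize() of a single value: SD reported as 0", stacklevel=2)
        return MeanSD(mean=float(arr[0]), sd=0.0)
    return MeanSD(mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
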