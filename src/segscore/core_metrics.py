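"""Pixel-level (traditional) segmentation evaluation.

A segmentation is compared with a reference by binarizing both images
(any non-zero pixel is foreground) and tallying true-positive,
false-positive and false-negative pixels.  Precision, recall and the
F-measure are derived from those tallies; the same arithmetic is shared
by the per-object evaluation in :mod:`segscore.object_eval`.

All three metrics are defined as 0 whenever their denominator is 0, so
comparing an empty segmentation with an empty reference scores 0, not 1
(empty-vs-empty is treated as "nothing was segmented", not "perfect").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PixelCounts",
    "MetricSet",
    "validate_label_image",
    "binarize",
    "pixel_counts",
    "metrics_from_counts",
    "evaluate_pixel_level",
]


@dataclass(frozen=True)
class PixelCounts:
    """Tally of true-positive, false-positive and false-negative pixels.

    True negatives are never stored: no implemented metric consumes them.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def __add__(self, other: "PixelCounts") -> "PixelCounts":
        return PixelCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    """Precision, recall and F-measure, each in [0, 1]."""

    precision: float
    recall: float
    f_measure: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.precision, self.recall, self.f_measure)


def validate_label_image(image, name: str = "image") -> np.ndarray:
    """Coerce *image* to a validated 2-D non-negative integer array.

    Labels are identities, not magnitudes: floating-point input is
    accepted only when every value is exactly integral.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(
            f"{name} must be a single-channel 2-D array, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.floor(arr)):
            raise ValueError(f"{name} has non-integral pixel values")
        arr = arr.astype(np.int64)
    elif np.issubdtype(arr.dtype, np.bool_):
        arr = arr.astype(np.int64)
    elif not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{name} has non-numeric dtype {arr.dtype}")
    if arr.min() < 0:
        raise ValueError(f"{name} has negative pixel values")
    return arr.astype(np.int64, copy=False)


def binarize(image) -> np.ndarray:
    """Foreground mask of a label image: 1 where the pixel is non-zero.

    Idempotent: the mask of a mask is itself.
    """
    arr = validate_label_image(image)
    return (arr > 0).astype(np.uint8)


def pixel_counts(gt_mask, test_mask) -> PixelCounts:
    """Count TP/FP/FN pixels between two binary masks.

    TP pixels are foreground in both masks, FP foreground only in the
    test mask, FN foreground only in the ground-truth mask.
    """
    gt = np.asarray(gt_mask).astype(bool)
    test = np.asarray(test_mask).astype(bool)
    if gt.shape != test.shape:
        raise ValueError(
            f"mask shapes differ: ground truth {gt.shape} vs test {test.shape}"
        )
    tp = int(np.count_nonzero(gt & test))
    fp = int(np.count_nonzero(~gt & test))
    fn = int(np.count_nonzero(gt & ~test))
    return PixelCounts(tp=tp, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics_from_counts(counts: PixelCounts) -> MetricSet:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F = 2PR/(P+R).

    Every 0/0 case yields 0.
    """
    p = _safe_ratio(counts.tp, counts.tp + counts.fp)
    r = _safe_ratio(counts.tp, counts.tp + counts.fn)
    f = _safe_ratio(2.0 * p * r, p + r)
    return MetricSet(precision=p, recall=r, f_measure=f)


def evaluate_pixel_level(gt, test) -> MetricSet:
    """Traditional pixel-level metrics for a ground-truth/test image pair."""
    return metrics_from_counts(pixel_counts(binarize(gt), binarize(test)))
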