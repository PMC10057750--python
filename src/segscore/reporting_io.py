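"""Raster I/O and report writing.

Label images are read from grayscale TIFF/PNG (8/16/32-bit integer) and
written as 16-bit PNG by default, or 32-bit TIFF when the label range
requires it.  Evaluation reports are written as an RFC-4180 CSV with one
row per ground-truth object plus a human-readable summary that lists the
discovered ground-truth intensity classes first, then pixel-level
metrics, then the per-object metrics.
"""

from __future__ import annotations

import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core_metrics import validate_label_image
from .object_eval import EvaluationReport

__all__ = [
    "read_label_image",
    "write_label_image",
    "rgb_to_labels",
    "report_to_frame",
    "format_summary",
    "write_report",
]

CSV_COLUMNS = [
    "image_id",
    "gt_id",
    "matched_test_id",
    "tp",
    "fp",
    "fn",
    "precision",
    "recall",
    "f_measure",
]


def read_label_image(path, rgb: bool = False) -> np.ndarray:
    """Read a label image from a grayscale (or, with *rgb*, color) file.

    Multi-channel input is rejected unless *rgb* is set, in which case
    it is converted through :func:`rgb_to_labels`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if not rgb:
            raise ValueError(
                f"{path} is multi-channel ({arr.shape}); pass rgb=True (or --rgb) "
                "to convert a color instance segmentation to labels"
            )
        return rgb_to_labels(arr)
    return validate_label_image(arr, str(path))


def write_label_image(image, path) -> None:
    """Write a label image; 16-bit PNG by default, 32-bit TIFF for large label ranges."""
    arr = validate_label_image(image)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.int32))
    else:
        if arr.max() > np.iinfo(np.uint16).max:
            raise ValueError(
                f"labels up to {arr.max()} exceed 16-bit PNG range; use a .tif path"
            )
        iio.imwrite(path, arr.astype(np.uint16))


def rgb_to_labels(image) -> np.ndarray:
    """Convert a color-coded instance segmentation to a label image.

    Each distinct color triple becomes one sequential positive label,
    ordered lexicographically by (R, G, B); black (0, 0, 0) maps to
    background 0.  Two disjoint regions of the same color receive the
    same label (no component splitting here).
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected an H x W x 3 color image, got shape {arr.shape}")
    arr = arr[:, :, :3]
    flat = arr.reshape(-1, 3)
    colors, inverse = np.unique(flat, axis=0, return_inverse=True)
    if len(colors) > 65535:
        raise ValueError(
            f"{len(colors)} distinct colors: this looks like a photograph, "
            "not a color-coded segmentation"
        )
    # lexicographic order from np.unique; black (if present) must map to 0
    label_of_color = np.zeros(len(colors), dtype=np.int32)
    next_label = 1
    for i, c in enumerate(colors):
        if (c == 0).all():
            label_of_color[i] = 0
        else:
            label_of_color[i] = next_label
            next_label += 1
    return label_of_color[inverse].reshape(arr.shape[:2])


def report_to_frame(report: EvaluationReport, image_id: str = "") -> pd.DataFrame:
    """Per-object rows of an evaluation as a DataFrame (one row per gt object)."""
    rows = []
    for r in report.per_object:
        rows.append(
            {
                "image_id": image_id,
                "gt_id": r.gt_id,
                "matched_test_id": r.matched_test_id,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "precision": r.metrics.precision,
                "recall": r.metrics.recall,
                "f_measure": r.metrics.f_measure,
            }
        )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame["matched_test_id"] = frame["matched_test_id"].astype("Int64")
    return frame


def format_summary(report: EvaluationReport, decimals: int = 4) -> str:
    """Human-readable summary: classes, then pixel-level, then per-object metrics."""
    d = decimals
    lines = [
        f"ground-truth intensity classes: {report.gt_intensity_classes}",
        f"ground-truth objects: {report.n_gt_objects}   "
        f"test objects: {report.n_test_objects}   "
        f"unmatched test objects: {report.n_unmatched_test}",
        "pixel-level:  "
        f"precision={report.pixel_level.precision:.{d}f}  "
        f"recall={report.pixel_level.recall:.{d}f}  "
        f"f-measure={report.pixel_level.f_measure:.{d}f}",
        "per-object:   "
        f"precision={report.object_level.precision:.{d}f}  "
        f"recall={report.object_level.recall:.{d}f}  "
        f"f-measure={report.object_level.f_measure:.{d}f}",
    ]
    return "\n".join(lines)


def write_report(
    report: EvaluationReport,
    csv_path,
    summary_path=None,
    image_id: str = "",
) -> None:
    """Write the per-object CSV and the summary (to *summary_path* or stdout)."""
    frame = report_to_frame(report, image_id=image_id)
    frame.to_csv(csv_path, index=False, lineterminator="\n", encoding="utf-8")
    text = format_summary(report)
    if summary_path is None:
        sys.stdout.write(text + "\n")
    else:
        Path(summary_path).write_text(text + "\n", encoding="utf-8")
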