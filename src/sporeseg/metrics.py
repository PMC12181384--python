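"""Pixel-level segmentation evaluation.

Predictions are compared with ground truth pixel by pixel; foreground
(spore/cell) is the positive class.  From the pooled confusion counts
the six standard metrics are computed:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)
    IoU         = TP / (TP + FP + FN)

Ratios with a zero denominator are reported as 0 with a logged warning
so batch evaluation never aborts.  Counts pooled over many patches give
micro-averaged metrics, identical to evaluating the concatenated masks.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_annotation import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "confusion_matrix_figure",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1", "iou")


@dataclass
class ConfusionCounts:
    """Pixel tallies; total() equals the number of evaluated pixels."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    iou: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion_counts(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-pixel confusion tally of a predicted mask against ground truth."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.pixels
    t = truth.pixels
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate the six metrics from pooled confusion counts."""
    if c.total() == 0:
        raise ValueError("no pixels evaluated (all counts zero)")
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total(), "accuracy"),
        precision=_ratio(c.tp, c.tp + c.fp, "precision"),
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1"),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, "iou"),
    )


def confusion_matrix_figure(c: ConfusionCounts, out: str | Path) -> None:
    """Render the 2x2 confusion matrix as an image and a CSV.

    Orientation: rows are the true class, columns the predicted class,
    ordered [foreground, background] - so the matrix is
    ``[[TP, FN], [FP, TN]]``.  The CSV is written next to the image with
    a ``.csv`` suffix.
    """
    out = Path(out)
    matrix = [[c.tp, c.fn], [c.fp, c.tn]]
    with open(out.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["", "pred_foreground", "pred_background"])
        writer.writerow(["true_foreground", c.tp, c.fn])
        writer.writerow(["true_background", c.fp, c.tn])

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.asarray(matrix, dtype=float), cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, f"{matrix[i][j]:,}", ha="center", va="center")
    ax.set_xticks([0, 1], ["foreground", "background"])
    ax.set_yticks([0, 1], ["foreground", "background"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
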