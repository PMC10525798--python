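"""Overlap metrics from one-vs-rest pixel confusion counts.

Dice = 2·TP/(FP+FN+2·TP), IoU = TP/(TP+FP+FN), Recall = TP/(TP+FN),
Precision = TP/(TP+FP), F1 = 2·TP/[(TP+FN)+(TP+FP)].

Degenerate denominators follow the both-empty convention: when a label is
absent from both masks (TP = FP = FN = 0) every metric is 1 (perfect
agreement on absence); otherwise an empty denominator yields 0.

``evaluate`` micro-averages by pooling counts over all samples per label
before computing metrics; macro-averaging is available as a flag. The
reported mean excludes the background label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import LabelScheme
from .errors import ShapeError, ValidationError

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "iou",
    "recall",
    "precision",
    "f1",
    "MetricsReport",
    "evaluate",
]

METRIC_NAMES = ("dice", "iou", "recall", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative", name)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_counts(pred: np.ndarray, truth: np.ndarray, label: int) -> ConfusionCounts:
    """One-vs-rest pixel counts for one label."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    p = pred == label
    t = truth == label
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, c: ConfusionCounts) -> float:
    if den == 0:
        return 1.0 if (c.tp == 0 and c.fp == 0 and c.fn == 0) else 0.0
    return num / den


def dice(c: ConfusionCounts) -> float:
    return _ratio(2.0 * c.tp, c.fp + c.fn + 2.0 * c.tp, c)


def iou(c: ConfusionCounts) -> float:
    return _ratio(float(c.tp), c.tp + c.fp + c.fn, c)


def recall(c: ConfusionCounts) -> float:
    return _ratio(float(c.tp), c.tp + c.fn, c)


def precision(c: ConfusionCounts) -> float:
    return _ratio(float(c.tp), c.tp + c.fp, c)


def f1(c: ConfusionCounts) -> float:
    return _ratio(2.0 * c.tp, (c.tp + c.fn) + (c.tp + c.fp), c)


def _metric_row(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dice": dice(c),
        "iou": iou(c),
        "recall": recall(c),
        "precision": precision(c),
        "f1": f1(c),
    }


@dataclass
class MetricsReport:
    """Per-label metric rows plus the unweighted mean over non-background labels."""

    per_label: dict[str, dict[str, float]]
    mean: dict[str, float]
    n_samples: int
    scheme: str
    average: str = "micro"

    def to_csv(self, path=None) -> str:
        lines = ["label," + ",".join(METRIC_NAMES)]
        for label, row in self.per_label.items():
            lines.append(label + "," + ",".join(f"{row[m]:.6f}" for m in METRIC_NAMES))
        lines.append("mean," + ",".join(f"{self.mean[m]:.6f}" for m in METRIC_NAMES))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    scheme: LabelScheme,
    average: str = "micro",
) -> MetricsReport:
    """Evaluate a prediction set against ground truth.

    ``micro`` pools confusion counts over all samples per label before
    computing metrics; ``macro`` averages per-sample metrics.
    """
    if len(preds) == 0 or len(truths) == 0:
        raise ValidationError("prediction/truth lists must be non-empty", "preds")
    if len(preds) != len(truths):
        raise ShapeError(f"{len(preds)} predictions vs {len(truths)} truths")
    if average not in ("micro", "macro"):
        raise ValidationError(f"average must be micro|macro, got {average!r}", "average")

    labels = list(range(scheme.num_labels))
    per_label: dict[str, dict[str, float]] = {}
    for lab in labels:
        if average == "micro":
            pooled = ConfusionCounts(0, 0, 0, 0)
            for p, t in zip(preds, truths):
                pooled = pooled + confusion_counts(p, t, lab)
            per_label[scheme.labels[lab]] = _metric_row(pooled)
        else:
            rows = [_metric_row(confusion_counts(p, t, lab)) for p, t in zip(preds, truths)]
            per_label[scheme.labels[lab]] = {
                m: float(np.mean([r[m] for r in rows])) for m in METRIC_NAMES
            }
    organ_labels = scheme.labels[1:]
    mean = {
        m: float(np.mean([per_label[lab][m] for lab in organ_labels]))
        for m in METRIC_NAMES
    }
    return MetricsReport(
        per_label=per_label,
        mean=mean,
        n_samples=len(preds),
        scheme=scheme.name,
        average=average,
    )
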