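"""Binary-classification metrics for melanoma (positive, label 1) vs
non-melanoma (label 0).

Definitions, with TP/TN/FP/FN the usual confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    F1          = TP / (TP + (FP + FN) / 2)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)

A metric whose denominator is zero raises :class:`UndefinedMetricError`
rather than silently returning 0 — with balanced corpora this is unreachable
in normal use, and silent zeros mask bugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ForwardContext, Tensor

__all__ = [
    "UndefinedMetricError", "ConfusionMatrix", "MetricsReport", "confusion",
    "accuracy", "f1", "sensitivity", "specificity", "precision", "report",
    "evaluate", "improvement_points",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero; names the metric."""

    def __init__(self, metric: str):
        super().__init__(f"{metric} is undefined: zero denominator")
        self.metric = metric


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer TP/FP/TN/FN counts, melanoma (1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, "
                                 f"got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_labels, true_labels) -> ConfusionMatrix:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("pred_labels and true_labels must be equal-length "
                         "1-D sequences")
    for arr, who in ((pred, "pred_labels"), (true, "true_labels")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{who} contains labels outside {{0, 1}}")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, metric: str) -> float:
    if den == 0:
        raise UndefinedMetricError(metric)
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def f1(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + 0.5 * (cm.fp + cm.fn), "f1")


def sensitivity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def precision(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fp, "precision")


@dataclass(frozen=True)
class MetricsReport:
    """All five metrics plus the confusion matrix they derive from."""

    confusion: ConfusionMatrix
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict:
        """Machine-readable form: raw values plus display rounding
        (4 dp for accuracy, 2 dp for the rest)."""
        cm = self.confusion
        return {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "accuracy": self.accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "display": {
                "accuracy": round(self.accuracy, 4),
                "f1": round(self.f1, 2),
                "sensitivity": round(self.sensitivity, 2),
                "specificity": round(self.specificity, 2),
                "precision": round(self.precision, 2),
            },
        }


def report(cm: ConfusionMatrix, strict: bool = True) -> MetricsReport:
    """Assemble all five metrics.

    With ``strict=False`` a metric whose denominator is zero (possible for a
    degenerate constant predictor) is reported as NaN instead of raising —
    ``evaluate`` uses this so that collapsed models can still be scored on
    accuracy.
    """
    values = {}
    for name, fn in (("accuracy", accuracy), ("f1", f1),
                     ("sensitivity", sensitivity),
                     ("specificity", specificity), ("precision", precision)):
        try:
            values[name] = fn(cm)
        except UndefinedMetricError:
            if strict:
                raise
            values[name] = float("nan")
    return MetricsReport(confusion=cm, **values)


def evaluate(model, images, class_labels, batch_size: int = 64) -> MetricsReport:
    """Evaluate a classifier on a labelled image set.

    ``model`` is anything with ``graph_forward(images, ctx)`` whose first (or
    only) output is an (n, 2) class-probability matrix — a DANN or a
    source-only classifier.  Predictions are argmax over the two classes;
    evaluation is deterministic given the model and the data order.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(class_labels)
    if labels.ndim != 1 or labels.shape[0] != images.shape[0]:
        raise ValueError("class_labels must be a 1-D array matching the "
                         "number of images (is the dataset labelled?)")
    ctx = ForwardContext(train=False)
    preds = []
    for start in range(0, images.shape[0], batch_size):
        out = model.graph_forward(Tensor(images[start:start + batch_size]), ctx)
        probs = out[0] if isinstance(out, tuple) else out
        preds.append(probs.data.argmax(axis=1))
    return report(confusion(np.concatenate(preds), labels), strict=False)


def improvement_points(acc_new: float, acc_ref: float) -> float:
    """Accuracy difference in percentage points (e.g. 0.7567 vs 0.5720
    -> 18.47)."""
    return round((acc_new - acc_ref) * 100.0, 2)
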