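"""Confusion-matrix construction and macro-averaged performance criteria.

Five criteria: accuracy (%), error rate (%), macro precision, macro recall,
and the F1 score computed as the harmonic mean of the two macro averages.
Per-class TP/FP/FN/TN come from a one-vs-rest reduction of the multiclass
confusion matrix; accuracy is trace/total (the multiclass generalization of
the binary (TP+TN)/(TP+TN+FP+FN) formula).  A class never predicted
contributes precision 0 (never observed: recall 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .preprocess import CLASSES


def confusion(y_true, y_pred, classes: tuple[str, ...] = CLASSES) -> np.ndarray:
    """Cross-tabulate counts; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise DataError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise DataError("cannot build a confusion matrix from empty inputs")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise DataError(f"unknown label in ({t!r}, {p!r})")
        cm[index[t], index[p]] += 1
    return cm


def per_class_counts(cm: np.ndarray, j: int) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for class j by one-vs-rest reduction."""
    cm = np.asarray(cm)
    if not 0 <= j < cm.shape[0]:
        raise DataError(f"class index {j} outside [0, {cm.shape[0]})")
    total = int(cm.sum())
    tp = int(cm[j, j])
    fp = int(cm[:, j].sum()) - tp
    fn = int(cm[j, :].sum()) - tp
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR / (P + R); 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricsReport:
    """The five criteria plus the underlying confusion matrix."""

    accuracy: float  # percent
    error_rate: float  # percent
    precision: float  # macro average, proportion
    recall: float  # macro average, proportion
    f1: float  # harmonic mean of macro precision and macro recall
    confusion_matrix: np.ndarray

    def to_dict(self) -> dict:
        # percentages to 4 d.p., proportions to 5 d.p. (reporting precision)
        return {
            "accuracy_pct": round(self.accuracy, 4),
            "error_rate_pct": round(self.error_rate, 4),
            "precision": round(self.precision, 5),
            "recall": round(self.recall, 5),
            "f1": round(self.f1, 5),
            "confusion_matrix": self.confusion_matrix.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def compute_metrics(cm: np.ndarray) -> MetricsReport:
    """All five criteria from a confusion matrix."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise DataError("empty confusion matrix")
    k = cm.shape[0]
    precisions, recalls = [], []
    for j in range(k):
        tp, fp, fn, _ = per_class_counts(cm, j)
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    precision = float(np.mean(precisions))
    recall = float(np.mean(recalls))
    accuracy = 100.0 * float(np.trace(cm)) / total
    return MetricsReport(
        accuracy=accuracy,
        error_rate=100.0 - accuracy,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        confusion_matrix=cm,
    )


def metrics_table(reports: dict[str, dict[str, MetricsReport]]):
    """Criteria x (model, phase) table as a pandas DataFrame.

    ``reports`` maps model name -> phase ('train'/'test') -> MetricsReport.
    """
    import pandas as pd

    rows = {}
    for model, phases in reports.items():
        for phase, rep in phases.items():
            d = rep.to_dict()
            rows[(model, phase)] = {
                "Accuracy (%)": d["accuracy_pct"],
                "Error rate (%)": d["error_rate_pct"],
                "Precision": d["precision"],
                "Recall": d["recall"],
                "F1 score": d["f1"],
            }
    return pd.DataFrame(rows).T
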