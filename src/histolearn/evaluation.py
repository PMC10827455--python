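"""Metrics and magnification-stratified reporting.

Standard binary-classification metrics over the benign/malignant labels:
confusion matrices (rows true, columns predicted, class order benign then
malignant), accuracy, per-class and macro F1, and per-class ROC curves with
trapezoidal AUC (equivalent to the Mann–Whitney pair statistic with
midpoint tie handling). Reports are computed per magnification tier and
assembled into one summary table, mirroring how histology classifiers are
conventionally evaluated tier by tier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .datamodel import CLASSES

logger = logging.getLogger("histolearn")

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_auc",
    "build_report",
    "magnification_report",
]


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """2×2 integer confusion matrix in (benign, malignant) order."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    for lab in (*true_labels, *predicted_labels):
        if lab not in CLASSES:
            raise ValueError(f"unknown label {lab!r}")
    if not true_labels:
        return np.zeros((2, 2), dtype=np.int64)
    return _skm.confusion_matrix(true_labels, predicted_labels,
                                 labels=list(CLASSES)).astype(np.int64)


def classification_metrics(confusion: np.ndarray) -> dict:
    """Accuracy and F1 from a confusion matrix.

    F1 = 2PR/(P+R) per class; a zero denominator in precision, recall or F1
    reports the metric as 0 with a warning.
    """
    cm = np.asarray(confusion)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("expected a non-negative 2x2 confusion matrix")
    n = cm.sum()
    out: dict = {"accuracy": float(np.trace(cm) / n) if n else 0.0,
                 "f1_per_class": {}, "precision_per_class": {},
                 "recall_per_class": {}}
    f1s = []
    for k, cls in enumerate(CLASSES):
        tp = cm[k, k]
        fp = cm[1 - k, k]
        fn = cm[k, 1 - k]
        if tp + fp == 0 or tp + fn == 0 or tp == 0:
            if tp + fp == 0 or tp + fn == 0:
                logger.warning("undefined precision/recall for class %s; "
                               "reporting 0", cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out["precision_per_class"][cls] = float(prec)
        out["recall_per_class"][cls] = float(rec)
        out["f1_per_class"][cls] = float(f1)
        f1s.append(f1)
    out["macro_f1"] = float(np.mean(f1s))
    return out


def roc_auc(scores: np.ndarray, true_labels) -> tuple[dict, dict]:
    """Per-class ROC curves and AUC from class-probability scores.

    ``scores`` is N×2 class probabilities (columns in class order). For
    each class the one-vs-rest curve is integrated trapezoidally over all
    thresholds; ties are handled by the midpoint (Mann–Whitney) convention.
    A single-class truth vector yields NaN AUC with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != len(CLASSES):
        raise ValueError(f"expected N×{len(CLASSES)} score matrix")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    y = np.array([CLASSES.index(l) for l in true_labels])
    roc_points: dict = {}
    auc_per_class: dict = {}
    for k, cls in enumerate(CLASSES):
        truth = (y == k).astype(int)
        if truth.size == 0 or truth.min() == truth.max():
            logger.warning("AUC undefined for class %s (single-class truth)", cls)
            roc_points[cls] = np.array([[0.0, 0.0], [1.0, 1.0]])
            auc_per_class[cls] = float("nan")
            continue
        fpr, tpr, _ = _skm.roc_curve(truth, scores[:, k])
        roc_points[cls] = np.column_stack([fpr, tpr])
        auc_per_class[cls] = float(_skm.auc(fpr, tpr))
    return roc_points, auc_per_class


@dataclass
class EvalReport:
    """Evaluation of one magnification tier (or "all")."""

    magnification: str
    confusion: np.ndarray
    accuracy: float
    f1_per_class: dict[str, float]
    macro_f1: float
    roc_points: dict[str, np.ndarray] = field(default_factory=dict)
    auc_per_class: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "magnification": self.magnification,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "f1_per_class": self.f1_per_class,
            "macro_f1": self.macro_f1,
            "auc_per_class": self.auc_per_class,
            "roc_points": {c: p.tolist() for c, p in self.roc_points.items()},
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_report(true_labels, scores: np.ndarray,
                 magnification: str = "all") -> EvalReport:
    """Full report from true labels and N×2 predicted probabilities."""
    scores = np.asarray(scores, dtype=float)
    pred = [CLASSES[int(k)] for k in scores.argmax(axis=1)]
    cm = confusion_matrix(true_labels, pred)
    m = classification_metrics(cm)
    points, aucs = roc_auc(scores, true_labels)
    return EvalReport(magnification=str(magnification), confusion=cm,
                      accuracy=m["accuracy"], f1_per_class=m["f1_per_class"],
                      macro_f1=m["macro_f1"], roc_points=points,
                      auc_per_class=aucs)


def magnification_report(reports: dict[int | str, EvalReport],
                         expected_tiers=(40, 100, 200, 400)) -> pd.DataFrame:
    """Summary table of accuracy/F1/AUC by magnification tier."""
    rows = []
    for tier in expected_tiers:
        rep = reports.get(tier, reports.get(str(tier)))
        if rep is None:
            logger.warning("missing evaluation report for tier %sX; "
                           "row omitted", tier)
            continue
        rows.append({
            "magnification": tier,
            "n": int(rep.confusion.sum()),
            "accuracy": rep.accuracy,
            "f1_benign": rep.f1_per_class.get("benign"),
            "f1_malignant": rep.f1_per_class.get("malignant"),
            "macro_f1": rep.macro_f1,
            "auc_benign": rep.auc_per_class.get("benign"),
            "auc_malignant": rep.auc_per_class.get("malignant"),
        })
    return pd.DataFrame(rows)
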