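"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, cross-validated
performance tables and random-forest feature-importance ranking.

Accuracy = (TP+TN)/(TP+FP+TN+FN); Precision = TP/(TP+FP);
Recall = TP/(TP+FN); F1 = harmonic mean of precision and recall.
AUC follows the Mann–Whitney convention (ties get half credit). Precision is
reported as missing (None) when no compound is predicted active, rather than
silently deflated to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .qsar import _as_array


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float | None
    recall: float
    f1: float | None
    auc: float | None
    counts: ConfusionCounts
    context: str = "test"  # train_cv | test

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "context": self.context}


def confusion_and_metrics(labels, confidences, threshold: float = 0.5,
                          context: str = "test") -> MetricsReport:
    """Threshold confidences and compute the four count-based metrics."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    y = np.asarray(labels).astype(int)
    conf = np.asarray(confidences, dtype=float)
    if len(y) == 0 or len(y) != len(conf):
        raise ValueError("labels and confidences must be non-empty and aligned")
    pred = (conf >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    return metrics_from_counts(counts, context=context)


def metrics_from_counts(counts: ConfusionCounts, auc: float | None = None,
                        context: str = "test") -> MetricsReport:
    n = counts.total
    accuracy = (counts.tp + counts.tn) / n
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    if precision is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, auc=auc, counts=counts, context=context)


def roc_auc(labels, confidences) -> tuple[float, pd.DataFrame]:
    """Mann–Whitney AUC plus the ROC curve points (fpr, tpr, threshold)."""
    y = np.asarray(labels).astype(int)
    conf = np.asarray(confidences, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    # Mann–Whitney statistic with half credit for ties — exact, not trapezoidal
    pos = conf[y == 1]
    neg = conf[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc_value = (greater + 0.5 * ties) / (len(pos) * len(neg))
    fpr, tpr, thr = roc_curve(y, conf)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc_value), curve


def crossval_report(model, X, y, folds: int = 10, seed: int = 0,
                    threshold: float = 0.5) -> pd.DataFrame:
    """Stratified k-fold CV metrics: one row per fold plus mean and sd rows.

    ``model`` is an unfitted sklearn-style classifier with predict_proba;
    it is cloned per fold so no state leaks between folds.
    """
    values, _, _ = _as_array(X)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires both classes")
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds minority-class count {counts.min()}")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(cv.split(values, y)):
        fitted = clone(model).fit(values[train_idx], y[train_idx])
        proba = fitted.predict_proba(values[test_idx])
        conf = proba[:, list(fitted.classes_).index(1)]
        report = confusion_and_metrics(y[test_idx], conf, threshold=threshold,
                                       context="train_cv")
        auc_value, _ = roc_auc(y[test_idx], conf)
        rows.append({"fold": fold, "accuracy": report.accuracy,
                     "precision": report.precision, "recall": report.recall,
                     "f1": report.f1, "auc": auc_value})
    frame = pd.DataFrame(rows)
    metric_cols = ["accuracy", "precision", "recall", "f1", "auc"]
    mean = frame[metric_cols].mean()
    sd = frame[metric_cols].std()
    frame = pd.concat([frame,
                       pd.DataFrame([{"fold": "mean", **mean.to_dict()},
                                     {"fold": "sd", **sd.to_dict()}])],
                      ignore_index=True)
    return frame


def feature_importance(model: RandomForestClassifier, descriptor_names,
                       top_k: int = 10) -> list[tuple[str, float]]:
    """Top-k RF impurity importances, sorted descending."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is not a fitted random forest")
    importances = np.asarray(model.feature_importances_)
    names = list(descriptor_names)
    if len(names) != len(importances):
        raise ValueError("descriptor_names length does not match the model")
    order = np.argsort(importances)[::-1][: min(top_k, len(names))]
    return [(names[i], float(importances[i])) for i in order]
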