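"""Classification metric suite: accuracy, macro PRF, ROC/AUC, kappa."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)

logger = logging.getLogger(__name__)


@dataclass
class Metrics:
    """Evaluation summary; percentages are on the 0-100 scale."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_accuracy: dict[int, float]
    confusion: np.ndarray            # row-normalized, percent
    confusion_counts: np.ndarray
    auc: float
    kappa: float
    roc: dict[int, tuple[np.ndarray, np.ndarray]] | None = None


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         proba: np.ndarray | None = None,
                         classes: np.ndarray | None = None,
                         keep_curves: bool = False) -> Metrics:
    """Compute the full metric suite from predictions.

    Macro averaging over the classes present in ``y_true``; absent
    classes are skipped with a log message.  AUC is one-vs-rest, macro
    averaged, and requires ``proba`` (columns ordered by ``classes``).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    present = np.isin(classes, y_true)
    if not present.all():
        logger.info("classes absent from the test set skipped in macro "
                    "averages: %s", classes[~present].tolist())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes[present], average="macro",
        zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    row_sum = cm.sum(axis=1, keepdims=True).astype(float)
    row_sum[row_sum == 0] = np.nan
    cm_pct = 100.0 * cm / row_sum
    per_class = {
        int(c): float(100.0 * cm[i, i] / cm[i].sum())
        for i, c in enumerate(classes) if cm[i].sum() > 0
    }
    auc = np.nan
    curves = None
    if proba is not None:
        proba = np.asarray(proba)
        auc = float(roc_auc_score(y_true, proba, multi_class="ovr",
                                  average="macro", labels=classes))
        if keep_curves:
            curves = {}
            for i, c in enumerate(classes[present]):
                fpr, tpr, _ = roc_curve((y_true == c).astype(int),
                                        proba[:, i])
                curves[int(c)] = (fpr, tpr)
    return Metrics(
        accuracy=float(100.0 * np.mean(y_true == y_pred)),
        precision=float(100.0 * prec),
        recall=float(100.0 * rec),
        f1=float(100.0 * f1),
        per_class_accuracy=per_class,
        confusion=cm_pct,
        confusion_counts=cm,
        auc=auc,
        kappa=float(cohen_kappa_score(y_true, y_pred)),
        roc=curves,
    )


def evaluate(model, X: np.ndarray, y: np.ndarray,
             keep_curves: bool = False) -> Metrics:
    """Evaluate a fitted classifier on a test set (order-invariant)."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(X)
    y_pred = model.classes_[proba.argmax(axis=1)]
    return evaluate_predictions(y, y_pred, proba, classes=model.classes_,
                                keep_curves=keep_curves)
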