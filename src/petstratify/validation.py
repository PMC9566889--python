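"""Cross-validation and performance reporting.

Stratified k-fold cross-validation with pooled out-of-fold predictions (one
confusion table from all held-out scores, so a single sensitivity/specificity
pair describes the cross-validated model), Mann–Whitney AUC, and the Pearson
χ² comparison of two classified proportions. p-values accompany statistics
but never drive any decision made here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .preprocess import FeatureMatrix
from .svm import SvmParams, _train_weights

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "auc",
    "kfold_scores",
    "compare_proportions_chi2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts; the positive class is the converter (label 1)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class PerformanceReport:
    confusion: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    auc: float | None
    per_subject: pd.DataFrame
    fold_assignment: dict


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def metrics_from_confusion(c: ConfusionCounts):
    """(sensitivity, specificity, accuracy); a rate with a zero denominator
    comes back as None (undefined), never NaN."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total
    return sens, spec, acc


def auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted ½
    (the Mann–Whitney U form of the ROC area)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def kfold_scores(features: FeatureMatrix, params: SvmParams | None = None,
                 k: int = 10, seed: int = 0, stratified: bool = True
                 ) -> PerformanceReport:
    """k-fold cross-validation with out-of-fold subject scores.

    Every subject is scored exactly once, by a model trained without it.
    Folds are stratified by class with seeded shuffling (configurable off);
    if a class has fewer members than k, k is reduced with a warning.
    Metrics come from the pooled out-of-fold predictions.
    """
    params = params or SvmParams()
    X, y = features.values, features.labels
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    if np.unique(y).size != 2:
        raise ValueError("cross-validation requires both classes")
    min_class = int(min((y == 0).sum(), (y == 1).sum()))
    if stratified and k > min_class:
        warnings.warn(
            f"reducing k from {k} to {min_class}: smallest class has {min_class} members",
            stacklevel=2,
        )
        k = min_class
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=k, shuffle=True, random_state=seed
    )
    gram = X @ X.T / params.kernel_scale**2 + params.kernel_offset

    oof_scores = np.empty(n)
    fold_assignment = {}
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        w, b = _train_weights(X[tr], y[tr], params, gram=gram[np.ix_(tr, tr)])
        oof_scores[te] = X[te] @ w + b
        for i in te:
            fold_assignment[features.subject_ids[i]] = fold

    y_pred = (oof_scores > 0).astype(int)
    conf = confusion_from_predictions(y, y_pred)
    sens, spec, acc = metrics_from_confusion(conf)
    report_auc = auc(oof_scores, y)
    per_subject = pd.DataFrame({
        "subject_id": features.subject_ids,
        "true_label": y,
        "oof_score": oof_scores,
        "predicted_label": y_pred,
        "fold": [fold_assignment[s] for s in features.subject_ids],
    })
    return PerformanceReport(confusion=conf, sensitivity=sens, specificity=spec,
                             accuracy=acc, auc=report_auc,
                             per_subject=per_subject, fold_assignment=fold_assignment)


def compare_proportions_chi2(k1: int, n1: int, k2: int, n2: int):
    """Pearson χ² (df=1, no continuity correction) comparing k1/n1 vs k2/n2.

    Returns (chi2, p). The 2×2 table is [[k1, n1−k1], [k2, n2−k2]].
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n for both groups")
    if n1 + n2 == 0:
        raise ValueError("both groups empty")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
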