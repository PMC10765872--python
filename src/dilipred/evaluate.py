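"""Binary-classification metrics and validation protocols.

Implements the confusion-matrix metric block (accuracy, sensitivity,
specificity, precision, F1), AUROC via the rank-probability definition
(probability that a random positive outscores a random negative, ties
counted one half) and AUPRC via step-wise average-precision integration,
plus hold-out evaluation and repeated stratified tenfold cross-validation.

Zero-denominator metrics are flagged as undefined (``None``), never
silently set to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import RepeatedStratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Metric block for one evaluation.

    Undefined metrics (zero denominators, e.g. specificity on an
    all-positive set) are ``None`` and listed in ``undefined``.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auroc: float | None
    auprc: float | None
    threshold: float = 0.5
    counts: ConfusionCounts | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "threshold": self.threshold,
            "undefined": list(self.undefined),
        }
        if self.counts is not None:
            d["confusion"] = {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            }
        return d


def _check_binary(y_true: np.ndarray) -> np.ndarray:
    y = np.asarray(y_true)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y_true must be binary (0/1)")
    return y.astype(int)


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a probability threshold (predict 1 iff p >= t)."""
    y = _check_binary(y_true)
    p = np.asarray(y_prob, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return ConfusionCounts(tp, fp, tn, fn)


def auroc(y_true, y_score) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) definition.

    Equals the probability that a uniformly drawn positive receives a
    higher score than a uniformly drawn negative, with ties counting 1/2.
    Raises on single-class input, where the quantity is undefined.
    """
    y = _check_binary(y_true)
    s = np.asarray(y_score, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: y_true contains a single class")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(y_true, y_score) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Average-precision convention: sum over distinct score thresholds of
    (recall increment) x (precision at that threshold); no interpolation.
    """
    y = _check_binary(y_true)
    s = np.asarray(y_score, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("AUPRC undefined: y_true contains a single class")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted)
    n_cum = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each tied-score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_d = tp_cum[distinct]
    n_d = n_cum[distinct]
    precision = tp_d / n_d
    recall = tp_d / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def metrics(
    y_true,
    y_prob,
    threshold: float = 0.5,
    counts: ConfusionCounts | None = None,
) -> MetricsReport:
    """Full metric block from labels and predicted probabilities."""
    y = _check_binary(y_true)
    p = np.asarray(y_prob, dtype=float)
    if counts is None:
        counts = confusion(y, p, threshold)
    c = counts
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = ratio(c.tp + c.tn, c.total, "accuracy")
    sen = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spe = ratio(c.tn, c.tn + c.fp, "specificity")
    pre = ratio(c.tp, c.tp + c.fp, "precision")
    if pre is None or sen is None or (pre + sen) == 0:
        undefined.append("f1")
        f1 = None
    else:
        f1 = 2 * pre * sen / (pre + sen)
    try:
        roc = auroc(y, p)
    except ValueError:
        undefined.append("auroc")
        roc = None
    try:
        prc = auprc(y, p)
    except ValueError:
        undefined.append("auprc")
        prc = None
    return MetricsReport(acc, sen, spe, pre, f1, roc, prc, threshold, c, undefined)


def holdout_evaluate(
    model,
    X_test: np.ndarray,
    y_test,
    threshold: float = 0.5,
    X_train: np.ndarray | None = None,
) -> MetricsReport:
    """Evaluate a fitted model on a held-out partition.

    ``model`` exposes ``predict_proba`` (sklearn convention: column 1 is
    the positive class) or a 1-d probability output. If ``X_train`` is
    supplied and is identical to ``X_test``, a warning is emitted — the
    hold-out contract requires disjoint partitions.
    """
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    if X_train is not None:
        X_train = np.asarray(X_train, dtype=float)
        if X_train.shape == X_test.shape and np.array_equal(X_train, X_test):
            warnings.warn("test set is identical to the training set", stacklevel=2)
    p = predict_proba_1d(model, X_test)
    return metrics(y_test, p, threshold)


def predict_proba_1d(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities as a flat vector from any model kind."""
    p = model.predict_proba(X)
    p = np.asarray(p, dtype=float)
    if p.ndim == 2:
        p = p[:, 1] if p.shape[1] == 2 else p.ravel()
    return p


def repeated_stratified_cv(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[list[MetricsReport], dict]:
    """Repeated stratified k-fold cross-validation.

    Data are shuffled (seeded) and split preserving class proportions; a
    fresh model from ``model_factory`` is fitted per fold. Returns the
    per-fold reports and the arithmetic mean of every defined metric.
    """
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or class_counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} members for {folds}-fold stratified CV"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    reports: list[MetricsReport] = []
    for train_idx, test_idx in splitter.split(X, y):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        p = predict_proba_1d(model, X[test_idx])
        reports.append(metrics(y[test_idx], p, threshold))
    keys = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auroc", "auprc")
    averages = {}
    for k in keys:
        vals = [getattr(r, k) for r in reports if getattr(r, k) is not None]
        averages[k] = float(np.mean(vals)) if vals else None
    return reports, averages


def roc_curve_points(y_true, y_score) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, threshold-sorted.

    Suitable both for plotting and for trapezoidal area integration.
    """
    y = _check_binary(y_true)
    s = np.asarray(y_score, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / max(tp[-1], 1)]
    fpr = np.r_[0.0, fp[distinct] / max(fp[-1], 1)]
    return np.column_stack([fpr, tpr])


def pr_curve_points(y_true, y_score) -> np.ndarray:
    """(recall, precision) points of the empirical PR curve."""
    y = _check_binary(y_true)
    s = np.asarray(y_score, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    n = np.arange(1, len(y) + 1)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    recall = tp[distinct] / max(int(y.sum()), 1)
    precision = tp[distinct] / n[distinct]
    return np.column_stack([recall, precision])
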