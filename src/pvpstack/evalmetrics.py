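"""Binary-classification metrics and the stratified cross-validation harness.

ACC, Sn, Sp and MCC follow the standard confusion-matrix definitions; AUC is
the rank-based Mann-Whitney statistic with midrank tie handling. Predicted
positive means probability strictly greater than the threshold (default 0.5).
Cross-validation pools out-of-fold predictions and computes one metric set on
the pooled vector, so thresholding is consistent with an independent test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None

    def rounded(self, ndigits: int = 3) -> "EvalMetrics":
        """Round-half-even to the reporting precision (3 decimals)."""
        return EvalMetrics(
            **{
                k: (round(v, ndigits) if v is not None else None)
                for k, v in asdict(self).items()
            }
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _as_labels(labels: Sequence[int]) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y.astype(int)


def confusion(
    labels: Sequence[int], predictions: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts with predicted-positive = probability > threshold."""
    y = _as_labels(labels)
    p = np.asarray(predictions, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    pred = p > threshold
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & pred)),
        tn=int(np.sum((y == 0) & ~pred)),
        fp=int(np.sum((y == 0) & pred)),
        fn=int(np.sum((y == 1) & ~pred)),
    )


def metrics_from_confusion(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(ACC, Sn, Sp, MCC) from confusion counts.

    MCC with any zero denominator factor is defined as 0. Sn/Sp raise if the
    corresponding class is absent.
    """
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    acc = (c.tp + c.tn) / c.n
    if c.tp + c.fn == 0:
        raise ValueError("no positive samples: Sn undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no negative samples: Sp undefined")
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return acc, sn, sp, mcc


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Midranks handle tied scores, so a constant score gives 0.5.
    """
    y = _as_labels(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> EvalMetrics:
    """All five metrics from labels and probability scores."""
    acc_, sn, sp, mcc = metrics_from_confusion(confusion(labels, scores, threshold))
    return EvalMetrics(acc=acc_, sn=sn, sp=sp, mcc=mcc, auc=auc(labels, scores))


def stratified_folds(labels: Sequence[int], folds: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (array of fold ids, 0..folds-1).

    Per-fold class proportions are within one sample of the global
    proportions. Requires at least ``folds`` samples of each class.
    """
    y = _as_labels(labels)
    for cls in (0, 1):
        if int(np.sum(y == cls)) < folds:
            raise ValueError(
                f"class {cls} has {int(np.sum(y == cls))} samples, fewer than "
                f"{folds} folds; reduce folds"
            )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def out_of_fold_probabilities(
    model_factory: Callable[[], object],
    features: np.ndarray,
    labels: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> np.ndarray:
    """Pooled out-of-fold probability-of-positive for every sample."""
    X = np.asarray(features, dtype=float)
    y = _as_labels(labels)
    if X.shape[0] != len(y):
        raise ValueError("features and labels are misaligned")
    assign = (
        stratified_folds(y, folds, seed) if fold_assignment is None else fold_assignment
    )
    oof = np.empty(len(y), dtype=float)
    for fold in np.unique(assign):
        test = assign == fold
        y_train = y[~test]
        if len(np.unique(y_train)) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(f"fold {fold} lost a class; use fewer folds")
        model = model_factory()
        model.fit(X[~test], y_train)
        oof[test] = positive_probability(model, X[test])
    return oof


def positive_probability(model, X: np.ndarray) -> np.ndarray:
    """Probability of the positive class from any fitted probability classifier."""
    proba = model.predict_proba(X)
    proba = np.asarray(proba)
    if proba.ndim == 1:
        return proba
    classes = list(getattr(model, "classes_", [0, 1]))
    return proba[:, classes.index(1)]


def crossvalidate(
    model_factory: Callable[[], object],
    features: np.ndarray,
    labels: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalMetrics:
    """Stratified k-fold CV: pool out-of-fold predictions, then score once."""
    oof = out_of_fold_probabilities(model_factory, features, labels, folds, seed)
    return evaluate(labels, oof, threshold)


def roc_points(labels: Sequence[int], scores: Sequence[float]) -> np.ndarray:
    """(FPR, TPR) pairs at every score threshold, for export/plotting."""
    y = _as_labels(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep last point of each tied-score run
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps[distinct] / max(len(y) - y.sum(), 1)]
    return np.column_stack([fpr, tpr])
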