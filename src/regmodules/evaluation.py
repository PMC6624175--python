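"""Cross-validated classification harness over RMES (or expression) features.

Quantifies how well the module enrichment features separate contexts:
k-fold cross-validated multi-class and one-vs-rest classification with
accuracy, per-class F1, F1-macro and F1-weighted, plus the dominant-class
baseline whose metrics are analytic functions of the class counts
(always predicting the majority class yields, one-vs-rest, accuracy
(S - S_c)/S and F1 = 0 for every class c, since it produces no true
positives).

Metric conventions: precision = tp/(tp+fp), recall = tp/(tp+fn), F1 =
2PR/(P+R), all defined as 0 in degenerate cases (tp = 0). Metrics are
computed on predictions pooled over the held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC

from .dataio import ContextLabels

MODES = ("multiclass", "one_vs_rest", "dominant_class")


@dataclass
class ConfusionCounts:
    """Binary confusion counts for one class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Pooled cross-validation metrics.

    For one_vs_rest and dominant_class modes, ``accuracy_per_class`` holds
    the per-class binary accuracies and ``accuracy`` their unweighted mean;
    for multiclass, ``accuracy`` is the pooled multi-class accuracy.
    """

    accuracy: float
    f1_per_class: dict[str, float]
    f1_macro: float
    f1_weighted: float
    fold_assignments: dict[str, int]
    accuracy_per_class: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_per_class": self.accuracy_per_class,
            "f1_per_class": self.f1_per_class,
            "f1_macro": self.f1_macro,
            "f1_weighted": self.f1_weighted,
        }


def accuracy(correct: int, total: int) -> float:
    if total < 1:
        raise ValueError("total must be at least 1")
    if correct > total:
        raise ValueError("correct cannot exceed total")
    return correct / total


def f1(counts: ConfusionCounts) -> float:
    """F1 = 2PR/(P+R); 0 whenever there are no true positives."""
    if counts.tp == 0:
        return 0.0
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    return 2 * precision * recall / (precision + recall)


def f1_macro(per_class_f1: Mapping[str, float]) -> float:
    if not per_class_f1:
        raise ValueError("per-class F1 mapping is empty")
    return float(np.mean(list(per_class_f1.values())))


def f1_weighted(per_class_f1: Mapping[str, float], supports: Mapping[str, int]) -> float:
    if not per_class_f1:
        raise ValueError("per-class F1 mapping is empty")
    total = sum(supports[c] for c in per_class_f1)
    if total == 0:
        raise ValueError("total support is zero")
    return float(sum(per_class_f1[c] * supports[c] for c in per_class_f1) / total)


def kfold_split(
    labels: ContextLabels, k: int, seed: int = 0, stratified: bool = True
) -> dict[str, int]:
    """Partition labeled samples into k near-equal folds.

    Stratified splitting preserves class proportions per fold (within one
    sample) and requires every class to have at least k members.
    Deterministic per seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    samples = list(labels.assignments)
    y = np.array([labels.assignments[s] for s in samples])
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"stratified {k}-fold split impossible: smallest class has "
                f"{counts.min()} samples"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignment[samples[i]] = fold
    return assignment


def default_classifier_spec():
    """The linear max-margin classifier used for the headline evaluation:
    L1-regularized, one-vs-rest, primal."""
    return LinearSVC(penalty="l1", dual=False)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive) -> ConfusionCounts:
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def evaluate(
    features: np.ndarray | pd.DataFrame | None,
    labels: ContextLabels,
    mode: str = "multiclass",
    classifier_spec: Callable | None = None,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> MetricsReport:
    """k-fold cross-validated classification metrics.

    ``features`` is samples x features, row-aligned with the labeled
    samples (as a DataFrame indexed by sample_id, or an array in label
    order); ``mode`` is ``multiclass``, ``one_vs_rest`` (one binary
    classifier per context, positives = that context) or
    ``dominant_class`` (predicts the most frequent training-fold class;
    needs no features). Out-of-fold predictions are pooled before metrics
    are computed.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    samples = list(labels.assignments)
    y = np.array([labels.assignments[s] for s in samples])

    X: np.ndarray | None = None
    if mode != "dominant_class":
        if features is None:
            raise ValueError(f"mode {mode!r} requires features")
        if isinstance(features, pd.DataFrame):
            missing = [s for s in samples if s not in features.index]
            if missing:
                raise ValueError(
                    f"labeled samples missing from features: {missing[:5]}"
                )
            X = features.loc[samples].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
            if X.shape[0] != len(samples):
                raise ValueError(
                    f"feature rows ({X.shape[0]}) do not align with labeled "
                    f"samples ({len(samples)})"
                )

    folds = kfold_split(labels, k=k, seed=seed, stratified=stratified)
    fold_arr = np.array([folds[s] for s in samples])
    spec = classifier_spec if classifier_spec is not None else default_classifier_spec

    supports = {c: int(np.sum(y == c)) for c in labels.contexts}

    if mode == "multiclass":
        y_pred = np.empty_like(y)
        for fold in range(k):
            test = fold_arr == fold
            clf = clone(spec())
            clf.fit(X[~test], y[~test])
            y_pred[test] = clf.predict(X[test])
        acc = accuracy(int(np.sum(y_pred == y)), len(y))
        per_f1 = {c: f1(_confusion(y, y_pred, c)) for c in labels.contexts}
        return MetricsReport(
            accuracy=acc,
            f1_per_class=per_f1,
            f1_macro=f1_macro(per_f1),
            f1_weighted=f1_weighted(per_f1, supports),
            fold_assignments=folds,
        )

    # binary reductions: one classifier (or baseline) per context
    per_acc: dict[str, float] = {}
    per_f1 = {}
    for context in labels.contexts:
        y_bin = (y == context).astype(int)
        y_pred = np.empty_like(y_bin)
        for fold in range(k):
            test = fold_arr == fold
            if mode == "dominant_class":
                train_counts = np.bincount(y_bin[~test], minlength=2)
                majority = int(np.argmax(train_counts))  # ties -> negative class
                y_pred[test] = majority
            else:
                clf = clone(spec())
                clf.fit(X[~test], y_bin[~test])
                y_pred[test] = clf.predict(X[test])
        per_acc[context] = accuracy(int(np.sum(y_pred == y_bin)), len(y_bin))
        per_f1[context] = f1(_confusion(y_bin, y_pred, 1))

    return MetricsReport(
        accuracy=float(np.mean(list(per_acc.values()))),
        f1_per_class=per_f1,
        f1_macro=f1_macro(per_f1),
        f1_weighted=f1_weighted(per_f1, supports),
        fold_assignments=folds,
        accuracy_per_class=per_acc,
    )
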