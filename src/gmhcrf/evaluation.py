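"""Grouped/stratified k-fold cross-validation and model comparison.

Grouped mode mirrors a leave-subjects-out protocol: each fold's test set
is all sequences of a disjoint subset of group ids.  Confusion matrices
follow the rows-true / columns-predicted convention with row-normalized
percentages; "average accuracy" is the mean of the diagonal percentages
and "pooled accuracy" the sequence-count-weighted rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import wilcoxon

from .exceptions import InputError
from .model_core import FeatureSequence, predict
from .training import TrainConfig, fit

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "CVReport",
    "ComparisonResult",
    "kfold_split",
    "cross_validate",
    "compare_models",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n) or np.any(self.counts < 0):
            raise InputError("counts must be a |V| x |V| non-negative matrix")

    @staticmethod
    def from_predictions(y_true, y_pred, labels) -> "ConfusionMatrix":
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return ConfusionMatrix(list(labels), counts)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Pooled (count-weighted) accuracy in [0, 1]."""
        n = self.n_total
        return float(np.trace(self.counts)) / n if n else float("nan")

    @property
    def percentages(self) -> np.ndarray:
        """Row-normalized percentages; empty rows yield NaN."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / row

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return np.diag(self.percentages)

    @property
    def average_accuracy(self) -> float:
        """Mean of per-class diagonal percentages (macro average)."""
        diag = self.per_class_accuracy
        return float(np.nanmean(diag))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise InputError("label sets differ")
        return ConfusionMatrix(self.labels, self.counts + other.counts)


@dataclass
class CVReport:
    """Per-fold confusion matrices plus pooled summary."""

    folds: List[ConfusionMatrix]
    pooled: ConfusionMatrix
    fold_accuracies: List[float]
    skipped_folds: List[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(
            self.fold_accuracies
        ) > 1 else 0.0


@dataclass
class ComparisonResult:
    """Paired fold-level comparison of two CV reports (A minus B)."""

    fold_differences: np.ndarray
    mean_difference: float
    p_value: float


def kfold_split(
    dataset: List[FeatureSequence],
    k: int,
    mode: str = "grouped",
    seed: int = 0,
) -> List[Tuple[List[FeatureSequence], List[FeatureSequence]]]:
    """k disjoint (train, test) partitions covering the dataset exactly once.

    grouped: fold test sets are unions of whole groups (leave-groups-out);
    stratified: class-balanced random folds.
    """
    if k < 2:
        raise InputError("need k >= 2")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    fold_of = np.empty(n, dtype=int)
    if mode == "grouped":
        groups = [s.group_id for s in dataset]
        if any(g is None for g in groups):
            raise InputError("grouped mode requires group_id on every sequence")
        uniq = sorted(set(groups))
        if len(uniq) < k:
            raise InputError(f"only {len(uniq)} distinct groups for k={k} folds")
        order = list(rng.permutation(len(uniq)))
        fold_of_group = {uniq[g]: i % k for i, g in enumerate(order)}
        for i, s in enumerate(dataset):
            fold_of[i] = fold_of_group[s.group_id]
    elif mode == "stratified":
        labels = [s.label for s in dataset]
        if any(v is None for v in labels):
            raise InputError("stratified mode requires labels on every sequence")
        for lab in sorted(set(labels)):
            idx = [i for i, v in enumerate(labels) if v == lab]
            idx = rng.permutation(idx)
            for j, i in enumerate(idx):
                fold_of[i] = j % k
    else:
        raise InputError(f"unknown split mode {mode!r}")
    out = []
    for f in range(k):
        test = [s for i, s in enumerate(dataset) if fold_of[i] == f]
        train = [s for i, s in enumerate(dataset) if fold_of[i] != f]
        out.append((train, test))
    return out


def cross_validate(
    dataset: List[FeatureSequence],
    config: TrainConfig,
    k: int = 10,
    mode: str = "grouped",
    seed: int = 0,
    fit_fn: Optional[Callable] = None,
    predict_fn: Optional[Callable] = None,
) -> CVReport:
    """Train from scratch on each fold's train split and score its test split.

    ``fit_fn(train, config) -> model`` and ``predict_fn(model, seq) -> label``
    default to the package trainer/predictor and may be swapped (e.g. an
    oracle) for protocol tests.  Folds whose training split misses a class
    are skipped with a warning and recorded in the report.
    """
    if any(s.label is None for s in dataset):
        raise InputError("cross_validate requires a fully labeled dataset")
    if fit_fn is None:
        fit_fn = lambda train, cfg: fit(train, cfg)[0]
    if predict_fn is None:
        predict_fn = predict
    labels = sorted({s.label for s in dataset})
    splits = kfold_split(dataset, k, mode=mode, seed=seed)
    folds, accs, skipped = [], [], []
    for f, (train, test) in enumerate(splits):
        if {s.label for s in train} != set(labels):
            logger.warning("fold %d training split is missing a class; skipped", f)
            skipped.append(f)
            continue
        model = fit_fn(train, config)
        y_true = [s.label for s in test]
        y_pred = [predict_fn(model, s) for s in test]
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, labels)
        folds.append(cm)
        accs.append(cm.accuracy)
    pooled = ConfusionMatrix(labels, sum(f.counts for f in folds)) if folds else (
        ConfusionMatrix(labels, np.zeros((len(labels), len(labels)), dtype=int))
    )
    return CVReport(
        folds=folds,
        pooled=pooled,
        fold_accuracies=accs,
        skipped_folds=skipped,
        meta={"k": k, "mode": mode, "seed": seed},
    )


def compare_models(reportA: CVReport, reportB: CVReport) -> ComparisonResult:
    """Paired two-sided Wilcoxon signed-rank over fold accuracies (A - B).

    Requires the two reports to be built on the same folds (same k, mode,
    seed).  With k <= 12 the exact null distribution is used.
    """
    if reportA.meta != reportB.meta or len(reportA.fold_accuracies) != len(
        reportB.fold_accuracies
    ):
        raise InputError("reports were not built on the same fold structure")
    a = np.asarray(reportA.fold_accuracies, dtype=float)
    b = np.asarray(reportB.fold_accuracies, dtype=float)
    d = a - b
    if np.all(d == 0):
        p = 1.0
    else:
        k = len(d)
        method = "exact" if k <= 12 else "auto"
        res = wilcoxon(
            d, alternative="two-sided", zero_method="wilcox", method=method
        )
        p = float(res.pvalue)
    return ComparisonResult(
        fold_differences=d, mean_difference=float(d.mean()), p_value=p
    )
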