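"""Nested cross-validation splitting and the binary-classification metric suite.

The splitting scheme is a repeated nested cross-validation: the dataset is
shuffled and partitioned into five disjoint outer folds; each outer fold in
turn serves as the held-out test set while the remaining 80% form the outer
training set. Within each outer loop, five inner repetitions each draw a
validation subset of 12.5% of the outer-training indices (10% of the total)
for tuning/early stopping. Metrics are computed from first principles:
confusion counts at a probability threshold, the ROC curve by a descending
threshold sweep with ties grouped, and AUC by the trapezoidal rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRIC_NAMES = (
    "auc",
    "acc",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "kappa",
    "mcc",
    "f1",
)


class FoldSizeError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class AUCUndefinedError(ValueError):
    """AUC requested for a score set containing only one class."""


class AggregationError(ValueError):
    pass


@dataclass
class OuterFold:
    test_idx: np.ndarray
    train_idx: np.ndarray
    inner_val_idx: list[np.ndarray] = field(default_factory=list)


@dataclass
class FoldPlan:
    """Nested cross-validation partition of ``n`` record indices."""

    n: int
    seed: int
    outer: list[OuterFold]

    def check_no_leakage(self) -> None:
        """Assert the partition invariants; raised on every evaluation run."""
        all_test = np.concatenate([f.test_idx for f in self.outer])
        if len(np.unique(all_test)) != self.n or len(all_test) != self.n:
            raise FoldSizeError("outer test folds do not partition the index set")
        for f in self.outer:
            if np.intersect1d(f.test_idx, f.train_idx).size:
                raise FoldSizeError("train/test overlap in an outer fold")
            for v in f.inner_val_idx:
                if np.intersect1d(v, f.test_idx).size:
                    raise FoldSizeError("inner validation overlaps outer test")


def make_fold_plan(
    n: int,
    seed: int,
    n_outer: int = 5,
    n_inner: int = 5,
    inner_fraction: float = 0.125,
) -> FoldPlan:
    """Shuffled 5-way outer partition with 5 inner validation draws per fold."""
    if n < 2 * n_outer:
        raise FoldSizeError(f"n={n} too small for {n_outer} outer folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_sets = np.array_split(perm, n_outer)
    outer = []
    for test_idx in test_sets:
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        n_val = max(1, round(inner_fraction * len(train_idx)))
        inner = [
            rng.choice(train_idx, size=n_val, replace=False)
            for _ in range(n_inner)
        ]
        outer.append(
            OuterFold(
                test_idx=np.sort(test_idx),
                train_idx=np.sort(train_idx),
                inner_val_idx=inner,
            )
        )
    plan = FoldPlan(n=n, seed=seed, outer=outer)
    plan.check_no_leakage()
    return plan


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with score >= threshold predicting the toxic class."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise AlignmentError("labels and scores differ in length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def roc_curve(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR), thresholds swept over distinct scores descending.

    Starts at (0, 0), ends at (1, 1); tied scores are grouped into one step.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise AUCUndefinedError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tps = np.cumsum(sorted_labels == 1)[distinct]
    fps = np.cumsum(sorted_labels == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return fpr, tpr


def trapezoidal_auc(labels, scores) -> float:
    """Area under the ROC curve by the trapezoidal rule."""
    fpr, tpr = roc_curve(labels, scores)
    return float(np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))


@dataclass(frozen=True)
class MetricReport:
    """The eight evaluation statistics for one prediction set."""

    auc: float
    acc: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    mcc: float
    f1: float
    roc: tuple[np.ndarray, np.ndarray] | None = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metric_suite(
    counts: ConfusionCounts, labels=None, scores=None, threshold: float = 0.5
) -> MetricReport:
    """All metrics from confusion counts (AUC/ROC when scores are supplied).

    ACC = (TP+TN)/N; BA = (sensitivity+specificity)/2; kappa via observed and
    chance agreement p_o/p_e; MCC from the product-of-margins denominator
    (returned as 0 with a warning when the denominator vanishes); F1 as the
    harmonic mean of precision and recall.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    if n == 0:
        raise ValueError("empty confusion table")
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n
    ba = 0.5 * (sens + spec)
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * sens / (precision + sens) if precision + sens else 0.0
    )
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1.0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting 0", RuntimeWarning)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    auc = float("nan")
    roc = None
    if labels is not None and scores is not None:
        roc = roc_curve(labels, scores)
        fpr, tpr = roc
        auc = float(np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))
    return MetricReport(
        auc=auc,
        acc=acc,
        balanced_accuracy=ba,
        sensitivity=sens,
        specificity=spec,
        kappa=float(kappa),
        mcc=float(mcc),
        f1=f1,
        roc=roc,
    )


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricReport:
    """Convenience: confusion + metric suite in one call."""
    return metric_suite(
        confusion(labels, scores, threshold), labels=labels, scores=scores
    )


def aggregate_folds(reports) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation per metric over fold reports.

    Returns a table indexed by metric with full-precision ``mean``/``std``
    columns and 3-decimal display roundings.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise AggregationError("need at least 2 fold reports to aggregate")
    rows = {}
    for name in METRIC_NAMES:
        vals = np.array([r.as_dict()[name] for r in reports], dtype=float)
        rows[name] = {
            "mean": float(np.mean(vals)),
            "std": float(np.std(vals, ddof=1)),
            "mean_display": round(float(np.mean(vals)), 3),
            "std_display": round(float(np.std(vals, ddof=1)), 3),
        }
    return pd.DataFrame(rows).T


def aggregate_values(values) -> tuple[float, float]:
    """Mean and sample std of a plain sequence (e.g. per-fold AUCs)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise AggregationError("need at least 2 values to aggregate")
    return float(values.mean()), float(values.std(ddof=1))


def single_split(n: int, seed: int, sizes=(0.7, 0.1, 0.2)) -> tuple[np.ndarray, ...]:
    """Alternative one-shot train/validation/test split (default 0.7:0.1:0.2)."""
    if not np.isclose(sum(sizes), 1.0):
        raise ValueError("split sizes must sum to 1")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(sizes[0] * n))
    n_val = int(round(sizes[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]
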