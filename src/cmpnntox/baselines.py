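"""Eleven classical fingerprint-based classifiers under the shared protocol.

These are comparators, not the contribution: each delegates to its standard
implementation (scikit-learn, XGBoost, LightGBM) with library-default
hyperparameters, run on Morgan fingerprints over the same fold plan as the
graph network so that comparisons differ only in the learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import FoldPlan, MetricReport, evaluate_predictions


class RegistryError(KeyError):
    pass


class DegenerateFoldError(ValueError):
    pass


def _build(name: str, seed: int, hyperparameters: dict):
    from lightgbm import LGBMClassifier
    from sklearn.ensemble import (
        AdaBoostClassifier,
        ExtraTreesClassifier,
        GradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import BernoulliNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    factories = {
        "Decision Tree": lambda: DecisionTreeClassifier(random_state=seed),
        "Nearest Neighbors": lambda: KNeighborsClassifier(),
        "Linear SVM": lambda: SVC(
            kernel="linear", probability=True, random_state=seed
        ),
        "Naive Bayes": lambda: BernoulliNB(),
        "Logistic Regression": lambda: LogisticRegression(max_iter=1000),
        "Random Forest": lambda: RandomForestClassifier(random_state=seed),
        "AdaBoost": lambda: AdaBoostClassifier(random_state=seed),
        "Gradient Boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "Extra Trees": lambda: ExtraTreesClassifier(random_state=seed),
        "LightGBM": lambda: LGBMClassifier(random_state=seed, verbose=-1),
        "XGBoost": lambda: XGBClassifier(
            random_state=seed, eval_metric="logloss"
        ),
    }
    if name not in factories:
        raise RegistryError(f"unknown baseline {name!r}")
    model = factories[name]()
    if hyperparameters:
        model.set_params(**hyperparameters)
    return model


BASELINE_NAMES = (
    "Decision Tree",
    "Nearest Neighbors",
    "Linear SVM",
    "Naive Bayes",
    "Logistic Regression",
    "Random Forest",
    "AdaBoost",
    "Gradient Boosting",
    "Extra Trees",
    "LightGBM",
    "XGBoost",
)


@dataclass(frozen=True)
class BaselineSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in BASELINE_NAMES:
            raise RegistryError(f"unknown baseline {self.name!r}")


def registry() -> tuple[str, ...]:
    """Names of the eleven registered classical methods."""
    return BASELINE_NAMES


def run_baseline(
    spec: BaselineSpec,
    folds: FoldPlan,
    features: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> list[MetricReport]:
    """Fit/score one baseline on every outer fold; returns per-fold metrics.

    Probability scores feed the AUC; thresholded labels feed the rest.
    """
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels are not row-aligned")
    folds.check_no_leakage()
    reports = []
    for fold in folds.outer:
        y_tr = labels[fold.train_idx]
        if len(np.unique(y_tr)) < 2:
            raise DegenerateFoldError("single-class training fold")
        model = _build(spec.name, spec.seed, spec.hyperparameters)
        model.fit(features[fold.train_idx], y_tr)
        proba = model.predict_proba(features[fold.test_idx])[:, 1]
        reports.append(
            evaluate_predictions(labels[fold.test_idx], proba, threshold)
        )
    return reports


def comparison_table(
    folds: FoldPlan,
    features: np.ndarray,
    labels: np.ndarray,
    names=BASELINE_NAMES,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (std) of every metric for each baseline, one row per model."""
    from .evaluation import METRIC_NAMES, aggregate_folds

    rows = []
    for name in names:
        reports = run_baseline(BaselineSpec(name=name, seed=seed), folds, features, labels)
        agg = aggregate_folds(reports)
        row = {"model": name}
        for metric in METRIC_NAMES:
            row[f"{metric}_mean"] = agg.loc[metric, "mean_display"]
            row[f"{metric}_std"] = agg.loc[metric, "std_display"]
        rows.append(row)
    return pd.DataFrame(rows)
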