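"""Classifier evaluation protocol: CV, univariate selection, grid search.

The feature table holds one row per (subject, band) — a subject therefore
contributes one row per frequency band.  Cross-validation defaults to
*subject-grouped* stratified folds so no subject straddles a train/test
boundary; plain row-level folds (which leak subjects and flatter the
accuracy) are available behind ``grouped=False`` for protocol parity.
Standardization for the linear models is fit inside training folds only,
via sklearn pipelines.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "EvalReport",
    "make_classifier",
    "crossval_eval",
    "univariate_accuracy",
    "select_features",
    "tune_and_validate",
    "DEFAULT_GRIDS",
]

CLASSIFIER_NAMES = ("LR", "SVM", "RF", "GBM")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"model__C": [0.1, 1.0, 10.0]},
    "SVM": {"model__C": [0.1, 1.0, 10.0], "model__gamma": ["scale", 0.1]},
    "RF": {"model__n_estimators": [100, 300], "model__max_depth": [None, 5]},
    "GBM": {"model__n_estimators": [100, 200], "model__num_leaves": [15, 31]},
}


@dataclasses.dataclass
class EvalReport:
    """Fold-averaged metrics per classifier, plus the fold assignment."""

    metrics: dict[str, dict[str, float]]
    fold_assignments: list[np.ndarray]
    confusions: dict[str, list[np.ndarray]]
    seed: int
    chosen_params: dict[str, list[dict]] = dataclasses.field(default_factory=dict)

    def accuracy(self, name: str) -> float:
        return self.metrics[name]["accuracy"]

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "seed": self.seed,
            "fold_sizes": [len(f) for f in self.fold_assignments],
            "chosen_params": self.chosen_params,
        }


def make_classifier(name: str, seed: int = 0) -> Pipeline:
    """Build a named classifier pipeline; linear models get a scaler."""
    if name == "LR":
        model = LogisticRegression(max_iter=2000, random_state=seed)
        steps = [("scale", StandardScaler()), ("model", model)]
    elif name == "SVM":
        model = SVC(random_state=seed)
        steps = [("scale", StandardScaler()), ("model", model)]
    elif name == "RF":
        model = RandomForestClassifier(n_estimators=200, random_state=seed)
        steps = [("model", model)]
    elif name == "GBM":
        model = LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1)
        steps = [("model", model)]
    else:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    return Pipeline(steps)


def _xyg(table: pd.DataFrame, feature_columns=None):
    feature_columns = feature_columns or [
        c for c in table.columns if c not in ("subject_id", "label", "band_name")
    ]
    X = table[feature_columns].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    groups = table["subject_id"].to_numpy()
    return X, y, groups, feature_columns


def _metrics_from_confusion(cm: np.ndarray) -> dict[str, float]:
    tn, fp, fn, tp = cm.ravel()
    acc = (tp + tn) / cm.sum()
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def _folds(y, groups, k, seed, grouped):
    if grouped:
        cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y, groups))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def crossval_eval(
    table: pd.DataFrame,
    classifiers=CLASSIFIER_NAMES,
    k: int = 5,
    seed: int = 0,
    grouped: bool = True,
    feature_columns=None,
) -> EvalReport:
    """Stratified (grouped) k-fold evaluation of the named classifiers."""
    X, y, groups, _ = _xyg(table, feature_columns)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("classification needs two classes in the table")
    n_units = len(np.unique(groups)) if grouped else len(y)
    if k > n_units / 2:
        raise ValueError(f"k={k} folds too many for {n_units} independent units")
    folds = _folds(y, groups, k, seed, grouped)
    metrics: dict[str, dict[str, float]] = {}
    confusions: dict[str, list[np.ndarray]] = {}
    for name in classifiers:
        cms = []
        for train, test in folds:
            clf = make_classifier(name, seed=seed)
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            cms.append(confusion_matrix(y[test], pred, labels=classes))
        per_fold = [_metrics_from_confusion(cm) for cm in cms]
        metrics[name] = {
            key: float(np.mean([m[key] for m in per_fold])) for key in per_fold[0]
        }
        confusions[name] = cms
    return EvalReport(
        metrics=metrics,
        fold_assignments=[test for _, test in folds],
        confusions=confusions,
        seed=seed,
    )


def univariate_accuracy(
    table: pd.DataFrame,
    feature_column: str,
    band_index: int | None = None,
    test_size: float = 0.3,
    classifier: str = "GBM",
    seed: int = 0,
) -> float:
    """Held-out accuracy of a single feature with the configured best model.

    The train/test split is stratified and fixed by ``seed``; ``band_index``
    restricts the table to one frequency band first.
    """
    if band_index is not None:
        table = table[table["band_index"] == band_index]
    X = table[[feature_column]].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    clf = make_classifier(classifier, seed=seed)
    clf.fit(Xtr, ytr)
    return float((clf.predict(Xte) == yte).mean())


def select_features(per_feature_acc: dict, threshold: float) -> list:
    """Indices/names whose univariate accuracy meets the threshold (>=)."""
    chosen = [idx for idx, acc in per_feature_acc.items() if acc >= threshold]
    if not chosen:
        warnings.warn(
            f"no feature reached accuracy {threshold}; falling back to all features",
            stacklevel=2,
        )
    return chosen


def tune_and_validate(
    table: pd.DataFrame,
    subset: list | None = None,
    grid: dict | None = None,
    classifier: str = "GBM",
    k: int = 10,
    inner_k: int = 3,
    seed: int = 0,
    grouped: bool = True,
) -> EvalReport:
    """Nested CV: grid search on training folds, metrics from outer folds."""
    feature_columns = list(subset) if subset else None
    X, y, groups, _ = _xyg(table, feature_columns)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("classification needs two classes in the table")
    grid = DEFAULT_GRIDS[classifier] if grid is None else grid
    if not grid:
        raise ValueError("empty parameter grid")
    folds = _folds(y, groups, k, seed, grouped)
    cms, chosen = [], []
    for train, test in folds:
        search = GridSearchCV(
            make_classifier(classifier, seed=seed),
            grid,
            cv=StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        search.fit(X[train], y[train])
        pred = search.predict(X[test])
        cms.append(confusion_matrix(y[test], pred, labels=classes))
        chosen.append(search.best_params_)
    per_fold = [_metrics_from_confusion(cm) for cm in cms]
    metrics = {
        classifier: {key: float(np.mean([m[key] for m in per_fold])) for key in per_fold[0]}
    }
    return EvalReport(
        metrics=metrics,
        fold_assignments=[test for _, test in folds],
        confusions={classifier: cms},
        seed=seed,
        chosen_params={classifier: chosen},
    )
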