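"""Pluggable binary classifiers under k-fold cross-validation.

Every model evaluation in the pipeline follows the same protocol: a seeded
stratified split into k folds, one train/predict pass per fold, and the
out-of-fold predictions merged back into original sample order before any
metric is computed. Merging first makes the metrics independent of fold
enumeration and gives a single confusion matrix over all samples — the
natural protocol when one class is rare and per-fold matrices would be
unstable.

The registry maps short names to constructors; any object with
``fit(X, y)``, ``predict(X)`` and a continuous score (``predict_proba`` or
``decision_function``) can be registered. Tree ensembles additionally expose
``feature_importances_``, which the importance-filter and the backward
elimination stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import ExpressionDataset
from .metrics import MetricVector, metric_vector

__all__ = ["ClassifierSpec", "CVResult", "kfold_cv", "evaluate",
           "make_classifier", "register_classifier", "CLASSIFIER_NAMES"]


def _make_rf(params, seed):
    return RandomForestClassifier(
        n_estimators=params.get("n_estimators", 500),
        random_state=seed, n_jobs=1,
        **{k: v for k, v in params.items() if k != "n_estimators"})


def _make_extratrees(params, seed):
    return ExtraTreesClassifier(
        n_estimators=params.get("n_estimators", 500),
        random_state=seed, n_jobs=1,
        **{k: v for k, v in params.items() if k != "n_estimators"})


def _make_gbt(params, seed):
    from xgboost import XGBClassifier
    defaults = dict(n_estimators=200, max_depth=3, verbosity=0, n_jobs=1)
    defaults.update(params)
    return XGBClassifier(random_state=seed, **defaults)


def _make_svm(params, seed):
    defaults = dict(kernel="rbf")
    defaults.update(params)
    return SVC(random_state=seed, **defaults)


def _make_knn(params, seed):
    defaults = dict(n_neighbors=5)
    defaults.update(params)
    return KNeighborsClassifier(**defaults)


_REGISTRY: dict[str, tuple[Callable, bool]] = {
    # name -> (factory(params, seed) -> estimator, has_importances)
    "rf": (_make_rf, True),
    "extratrees": (_make_extratrees, True),
    "gbt": (_make_gbt, True),
    "svm": (_make_svm, False),
    "knn": (_make_knn, False),
}

CLASSIFIER_NAMES = tuple(_REGISTRY)


def register_classifier(name: str, factory: Callable, has_importances: bool = False):
    """Add a classifier to the registry (factory(params, seed) -> estimator)."""
    _REGISTRY[name] = (factory, has_importances)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier plus hyperparameter overrides and a seed."""

    name: str = "rf"
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in _REGISTRY:
            raise ValueError(f"unknown classifier {self.name!r}; "
                             f"registered: {sorted(_REGISTRY)}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))

    @property
    def has_importances(self) -> bool:
        return _REGISTRY[self.name][1]

    def build(self, seed: int | None = None):
        factory, _ = _REGISTRY[self.name]
        return factory(dict(self.hyperparameters),
                       self.seed if seed is None else seed)


def make_classifier(spec: ClassifierSpec, seed: int | None = None):
    return spec.build(seed)


@dataclass(frozen=True)
class CVResult:
    """Merged out-of-fold predictions of one cross-validated model."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fold_assignment: np.ndarray
    mean_importances: np.ndarray | None  # per-gene, None for svm/knn


def _score_of(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def kfold_cv(
    ds: ExpressionDataset,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """Stratified k-fold CV with out-of-fold predictions merged in sample order.

    Per-feature importances, where the model exposes them, are averaged over
    the k trained models.
    """
    n_neg, n_pos = ds.class_counts()
    if stratified and min(n_neg, n_pos) < k:
        raise ValueError(
            f"minority class has {min(n_neg, n_pos)} samples < k={k}; "
            f"use a smaller k")
    if ds.n_samples < k:
        raise ValueError(f"n_samples={ds.n_samples} < k={k}")
    splitter = (StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                if stratified else
                KFold(n_splits=k, shuffle=True, random_state=seed))
    X, y = ds.values, ds.labels
    y_pred = np.empty(ds.n_samples, dtype=int)
    scores = np.empty(ds.n_samples, dtype=float)
    folds = np.empty(ds.n_samples, dtype=int)
    importances = []
    for fold_id, (train, test) in enumerate(splitter.split(X, y)):
        model = spec.build(seed=seed + fold_id)
        model.fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
        scores[test] = _score_of(model, X[test])
        folds[test] = fold_id
        if spec.has_importances:
            importances.append(np.asarray(model.feature_importances_, dtype=float))
    mean_imp = np.mean(importances, axis=0) if importances else None
    return CVResult(y_true=y.copy(), y_pred=y_pred, scores=scores,
                    fold_assignment=folds, mean_importances=mean_imp)


def evaluate(
    ds: ExpressionDataset,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> MetricVector:
    """Cross-validate and reduce the merged predictions to a MetricVector."""
    cv = kfold_cv(ds, spec, k=k, seed=seed, stratified=stratified)
    return metric_vector(cv.y_true, cv.y_pred, cv.scores)
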