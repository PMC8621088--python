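"""Five-algorithm training layer: grid search under stratified 5-fold CV.

Algorithms: Gaussian naive Bayes (``nb``), decision tree (``dt``),
random forest (``rf``), multinomial logistic regression (``lr``) and
gradient-boosted trees (``xgb``).  Each has a default hyperparameter
grid; grid points are scored by macro-F1 (robust to class imbalance)
with stratified k-fold cross-validation, and the best point is refit on
the full training input.

Notes on the default grids
--------------------------
* ``nb`` is a Gaussian naive Bayes with a variance-smoothing grid; an
  ``svm`` entry (C / gamma / kernel) is also registered for users who
  want a kernel baseline.
* ``xgb`` has no ``max_features``; per-tree column subsampling
  (``colsample_bytree``) plays that role.  ``max_depth=None`` maps to 0
  (unlimited) in XGBoost.
* ``lr`` defaults to an L2 penalty (lbfgs); an L1 grid requires the
  saga solver and is much slower, so it is not in the default grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import SchemaError

ALGORITHMS = ("nb", "dt", "rf", "lr", "xgb", "svm")

_DEPTHS = [10, 20, 30, 40, 50, None]
_TREES = [20, 40, 60, 80, 100, 200, 500, 1000, 1500]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "nb": {"var_smoothing": [1e-9, 1e-7, 1e-5, 1e-3]},
    "lr": {"penalty": ["l2"], "C": [0.001, 0.01, 0.1, 1, 10, 100, 1000]},
    "dt": {
        "criterion": ["gini", "entropy"],
        "max_depth": _DEPTHS,
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 5, 10],
    },
    "rf": {
        "bootstrap": [True, False],
        "max_depth": _DEPTHS,
        "max_features": ["sqrt", None],
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 5, 10],
        "n_estimators": _TREES,
    },
    "xgb": {
        "max_depth": [10, 20, 30, 40, 50, 0],
        "colsample_bytree": [1.0, 0.3],
        "min_child_weight": [1, 2, 4],
        "n_estimators": _TREES,
    },
    "svm": {
        "C": [0.001, 0.01, 0.1, 1, 10, 100, 1000],
        "gamma": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "kernel": ["rbf", "linear"],
    },
}


def build_estimator(algorithm: str, seed: int = 0):
    """Fresh unfitted estimator for one of the registered algorithms."""
    if algorithm == "nb":
        return GaussianNB()
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "lr":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if algorithm == "xgb":
        return XGBClassifier(random_state=seed, tree_method="hist", n_jobs=1,
                             verbosity=0, eval_metric="mlogloss")
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ModelSpec:
    """Training recipe: algorithm, grid, CV folds and scoring metric."""

    algorithm: str
    grid: dict[str, list] | None = None
    cv_folds: int = 5
    scoring: str = "f1_macro"

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}


@dataclass
class TrainedModel:
    """A fitted predictor plus the bookkeeping needed to reuse it safely."""

    spec: ModelSpec
    best_params: dict[str, Any]
    fold_scores: list[float]
    estimator: Any
    feature_names: tuple[str, ...]
    classes: tuple
    label_encoder: LabelEncoder

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            if missing or extra:
                raise SchemaError(
                    f"feature schema mismatch: missing {missing[:5]}, extra {extra[:5]}")
            return X.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} features, got shape {X.shape}")
        return X

    def predict(self, X) -> np.ndarray:
        """Predicted labels (catalog values), one per row."""
        Xa = self._align(X)
        if len(Xa) == 0:
            return np.array([], dtype=object)
        encoded = self.estimator.predict(Xa)
        return self.label_encoder.inverse_transform(np.asarray(encoded, dtype=int))

    def predict_scores(self, X) -> pd.DataFrame:
        """Per-class probability matrix; columns in catalog (sorted-label) order."""
        Xa = self._align(X)
        proba = self.estimator.predict_proba(Xa)
        cols = self.label_encoder.inverse_transform(
            np.asarray(self.estimator.classes_, dtype=int))
        df = pd.DataFrame(proba, columns=cols)
        return df.loc[:, list(self.classes)]


def grid_search_cv(X, y, spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Exhaustive grid search with stratified k-fold CV, then refit.

    Deterministic given the seed: the CV shuffling, every estimator and
    the grid enumeration order are all seeded or fixed.
    """
    feature_names = (tuple(X.columns) if isinstance(X, pd.DataFrame)
                     else tuple(f"f{i}" for i in range(np.asarray(X).shape[1])))
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    ya = np.asarray(y)
    encoder = LabelEncoder().fit(ya)
    y_enc = encoder.transform(ya)
    classes = tuple(encoder.classes_)

    if len(classes) == 1:
        est = DummyClassifier(strategy="prior").fit(Xa, y_enc)
        return TrainedModel(spec, {}, [1.0] * spec.cv_folds, est,
                            feature_names, classes, encoder)

    _, counts = np.unique(y_enc, return_counts=True)
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than "
            f"cv_folds={spec.cv_folds}; lower cv_folds or raise the "
            "low-count class cutoff")

    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        build_estimator(spec.algorithm, seed), spec.grid,
        scoring=spec.scoring, cv=cv, refit=True, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(Xa, y_enc)
    best = search.best_index_
    fold_scores = [float(search.cv_results_[f"split{i}_test_score"][best])
                   for i in range(spec.cv_folds)]
    return TrainedModel(spec, dict(search.best_params_), fold_scores,
                        search.best_estimator_, feature_names, classes, encoder)
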