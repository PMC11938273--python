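"""The six classifier families and their random-search spaces.

Five families come from scikit-learn / XGBoost.  The explainable boosting
machine (EBM) is implemented here as a cyclic gradient-boosted generalized
additive model: one shape function per feature, grown by round-robin
boosting of tiny single-feature regression trees on the logistic gradient.
The additive structure keeps every feature's contribution inspectable via
``shape_function``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from ..exceptions import ConfigurationError

__all__ = ["EBMClassifier", "ModelSpec", "MODEL_FAMILIES", "make_estimator", "sample_params"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class EBMClassifier(ClassifierMixin, BaseEstimator):
    """Explainable boosting machine: an additive model of per-feature shape
    functions fit by cyclic gradient boosting with logistic loss.

    Each boosting cycle visits the features round-robin; for each feature a
    shallow regression tree (``max_leaves`` leaves) is fit to the current
    logistic gradient using that feature alone, and added to the feature's
    shape function scaled by ``learning_rate``.  Multiclass targets are
    handled one-vs-rest with probability normalization.
    """

    def __init__(
        self,
        n_cycles: int = 40,
        learning_rate: float = 0.2,
        max_leaves: int = 3,
        random_state: int | None = None,
    ):
        self.n_cycles = n_cycles
        self.learning_rate = learning_rate
        self.max_leaves = max_leaves
        self.random_state = random_state

    def _fit_binary(self, X: np.ndarray, y01: np.ndarray):
        n, p = X.shape
        base = y01.mean()
        base = min(max(base, 1e-6), 1 - 1e-6)
        intercept = float(np.log(base / (1 - base)))
        trees: list[list[DecisionTreeRegressor]] = [[] for _ in range(p)]
        margin = np.full(n, intercept)
        for _ in range(self.n_cycles):
            for j in range(p):
                grad = y01 - _sigmoid(margin)
                tree = DecisionTreeRegressor(
                    max_leaf_nodes=self.max_leaves, random_state=self.random_state
                )
                tree.fit(X[:, [j]], grad)
                update = self.learning_rate * tree.predict(X[:, [j]])
                margin += update
                trees[j].append(tree)
        return intercept, trees

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("EBMClassifier needs at least two classes")
        self.n_features_in_ = X.shape[1]
        self._binary_models = []
        if len(self.classes_) == 2:
            y01 = (y == self.classes_[1]).astype(float)
            self._binary_models.append(self._fit_binary(X, y01))
        else:
            for cls in self.classes_:
                self._binary_models.append(self._fit_binary(X, (y == cls).astype(float)))
        return self

    def _binary_margin(self, model, X: np.ndarray) -> np.ndarray:
        intercept, trees = model
        margin = np.full(len(X), intercept)
        for j, feature_trees in enumerate(trees):
            col = X[:, [j]]
            for tree in feature_trees:
                margin += self.learning_rate * tree.predict(col)
        return margin

    def predict_proba(self, X):
        check_is_fitted(self, "_binary_models")
        X = np.asarray(X, dtype=float)
        if len(self.classes_) == 2:
            p1 = _sigmoid(self._binary_margin(self._binary_models[0], X))
            return np.column_stack([1 - p1, p1])
        raw = np.column_stack(
            [_sigmoid(self._binary_margin(m, X)) for m in self._binary_models]
        )
        return raw / raw.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def shape_function(self, j: int, grid: np.ndarray, class_index: int = -1) -> np.ndarray:
        """Additive contribution of feature ``j`` along ``grid`` (margin
        units, relative to the intercept)."""
        check_is_fitted(self, "_binary_models")
        _, trees = self._binary_models[class_index if class_index >= 0 else 0]
        col = np.asarray(grid, dtype=float).reshape(-1, 1)
        out = np.zeros(len(col))
        for tree in trees[j]:
            out += self.learning_rate * tree.predict(col)
        return out


# ---------------------------------------------------------------------------
# Family registry and random-search spaces
#
# Space entries are either a list of candidate values or a distribution
# tuple: ("loguniform", lo, hi), ("uniform", lo, hi), ("int", lo, hi).


MODEL_FAMILIES: dict[str, dict[str, Any]] = {
    "svm": {
        "factory": lambda params, seed: SVC(
            probability=True, random_state=seed, **params
        ),
        "space": {
            "C": ("loguniform", 1e-2, 1e2),
            "gamma": ["scale", "auto"],
            "kernel": ["rbf", "linear"],
        },
    },
    "logistic_regression": {
        "factory": lambda params, seed: LogisticRegression(
            max_iter=5000, random_state=seed, **params
        ),
        "space": {"C": ("loguniform", 1e-3, 1e2)},
    },
    "knn": {
        "factory": lambda params, seed: KNeighborsClassifier(**params),
        "space": {
            "n_neighbors": ("int", 1, 15),
            "weights": ["uniform", "distance"],
        },
    },
    "random_forest": {
        "factory": lambda params, seed: RandomForestClassifier(
            random_state=seed, **params
        ),
        "space": {
            "n_estimators": ("int", 100, 300),
            "max_depth": [None, 3, 5, 10],
            "max_features": ["sqrt", 0.5],
            "min_samples_leaf": ("int", 1, 5),
        },
    },
    "xgboost": {
        "factory": lambda params, seed: XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
            verbosity=0,
            **params,
        ),
        "space": {
            "n_estimators": ("int", 50, 300),
            "max_depth": ("int", 2, 6),
            "learning_rate": ("loguniform", 0.01, 0.3),
            "subsample": ("uniform", 0.6, 1.0),
        },
    },
    "ebm": {
        "factory": lambda params, seed: EBMClassifier(random_state=seed, **params),
        "space": {
            "n_cycles": ("int", 20, 60),
            "learning_rate": ("loguniform", 0.05, 0.5),
            "max_leaves": ("int", 2, 4),
        },
    },
}


@dataclass
class ModelSpec:
    """One classifier family plus its hyperparameter search budget."""

    family: str
    space: dict | None = None
    n_random_draws: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; choose from {sorted(MODEL_FAMILIES)}"
            )
        if self.space is None:
            self.space = dict(MODEL_FAMILIES[self.family]["space"])
        if not self.space:
            raise ConfigurationError("hyperparameter space must be non-empty")


def sample_params(space: dict, rng: np.random.Generator) -> dict:
    """Draw one hyperparameter set from a search space."""
    params = {}
    for name, spec in space.items():
        if isinstance(spec, list):
            params[name] = spec[rng.integers(0, len(spec))]
        elif isinstance(spec, tuple) and spec[0] == "loguniform":
            params[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif isinstance(spec, tuple) and spec[0] == "uniform":
            params[name] = float(rng.uniform(spec[1], spec[2]))
        elif isinstance(spec, tuple) and spec[0] == "int":
            params[name] = int(rng.integers(spec[1], spec[2] + 1))
        else:
            raise ConfigurationError(f"malformed space entry {name!r}: {spec!r}")
    return params


def make_estimator(family: str, params: dict, seed: int | None = None):
    """Instantiate a classifier of ``family`` with ``params``."""
    if family not in MODEL_FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    return MODEL_FAMILIES[family]["factory"](dict(params), seed)
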