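"""Fold-wise preprocessing: standardization, kNN imputation, mRMR feature
selection and SMOTE class balancing.

Everything here is fitted on training rows only and applied unchanged to
test rows — the no-leakage contract of Monte Carlo cross-validation.
``MRMRSelector`` and ``SMOTEOversampler`` follow scikit-learn estimator
conventions (``get_params``/``set_params``, fitted attributes with a
trailing underscore) so they compose with sklearn pipelines and
``clone``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.impute import KNNImputer
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from ..exceptions import ImputationError, ResamplingError

__all__ = [
    "StandardizerState",
    "fit_apply_standardizer",
    "knn_impute",
    "MRMRSelector",
    "SMOTEOversampler",
]


@dataclass(frozen=True)
class StandardizerState:
    """Train-set per-feature location/scale, applied unchanged to test."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def fit_apply_standardizer(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, StandardizerState]:
    """Z-score columns with train-set statistics (missing values ignored).

    Zero-variance columns are centered but not divided (scale 1), with a
    warning — their z-score is undefined.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(train, axis=0)
        sd = np.nanstd(train, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    zero = ~(sd > 0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance column(s) centered without scaling",
            stacklevel=2,
        )
    sd = np.where(zero, 1.0, sd)
    state = StandardizerState(mean=mean, sd=sd)
    return state.transform(train), None if test is None else state.transform(test), state


def knn_impute(X: np.ndarray, k: int = 5) -> np.ndarray:
    """Fill missing cells with the feature mean over the k nearest rows
    (nan-aware Euclidean distance on mutually observed features).
    Observed cells are never altered."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).all(axis=1).any():
        raise ImputationError("row with no observed feature cannot be imputed")
    if not np.isnan(X).any():
        return X.copy()
    imputer = KNNImputer(n_neighbors=min(k, len(X) - 1) or 1, weights="uniform")
    return imputer.fit_transform(X)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Minimum-redundancy maximum-relevance greedy feature selection.

    Relevance is the one-way ANOVA F statistic of a feature against the
    class label; redundancy is the mean absolute Pearson correlation with
    the already-selected features; candidates are ranked by the quotient
    relevance / redundancy.  The first pick is the most relevant feature;
    ties break toward the lower column index, so a constant feature
    (relevance 0) is never preferred.

    Parameters
    ----------
    n_features_to_select : int
        How many features to keep (clipped to the number of columns).
    """

    _EPS = 1e-12

    def __init__(self, n_features_to_select: int = 10):
        self.n_features_to_select = n_features_to_select

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.isnan(X).any():
            raise ValueError("MRMRSelector requires a complete matrix; impute first")
        n_features = X.shape[1]
        n_select = min(self.n_features_to_select, n_features)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant features yield F=nan
            relevance, _ = f_classif(X, y)
        relevance = np.where(np.isfinite(relevance), relevance, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.abs(np.corrcoef(X, rowvar=False))
        if corr.ndim == 0:  # single feature
            corr = np.ones((1, 1))
        corr = np.where(np.isfinite(corr), corr, 0.0)

        selected: list[int] = [int(np.argmax(relevance))]
        remaining = [j for j in range(n_features) if j != selected[0]]
        while len(selected) < n_select:
            redundancy = corr[np.ix_(remaining, selected)].mean(axis=1)
            scores = relevance[remaining] / np.maximum(redundancy, self._EPS)
            best = remaining[int(np.argmax(scores))]
            selected.append(best)
            remaining.remove(best)

        self.n_features_in_ = n_features
        self.relevance_ = relevance
        self.ranking_ = selected
        support = np.zeros(n_features, dtype=bool)
        support[selected] = True
        self.support_ = support
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class SMOTEOversampler(BaseEstimator):
    """Synthetic minority oversampling (SMOTE).

    Every non-majority class is upsampled to the majority count.  A
    synthetic sample is ``x + lam * (x_neighbor - x)`` with ``x`` a random
    member of the class, ``x_neighbor`` one of its ``k_neighbors`` nearest
    same-class rows and ``lam ~ U(0, 1)``.  Original rows are returned
    verbatim, first.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.isnan(X).any():
            raise ValueError("SMOTE requires a complete matrix; impute first")
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        majority = counts.max()
        X_out, y_out = [X], [y]
        for cls, count in zip(classes, counts):
            deficit = int(majority - count)
            if deficit == 0:
                continue
            if count < 2:
                raise ResamplingError(
                    f"class {cls!r} has {count} member(s); SMOTE needs >= 2"
                )
            members = X[y == cls]
            k = min(self.k_neighbors, count - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
            _, neighbor_idx = nn.kneighbors(members)  # col 0 is self
            base = rng.integers(0, count, size=deficit)
            pick = rng.integers(1, k + 1, size=deficit)
            lam = rng.random(size=deficit)
            anchors = members[base]
            partners = members[neighbor_idx[base, pick]]
            synth = anchors + lam[:, None] * (partners - anchors)
            X_out.append(synth)
            y_out.append(np.full(deficit, cls, dtype=y.dtype))
        return np.vstack(X_out), np.concatenate(y_out)
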