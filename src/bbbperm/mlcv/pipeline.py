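"""Monte Carlo cross-validation of the permeability classifiers.

The study design: 100 random 80/20 train/test splits; within every fold the
training rows alone drive standardization, kNN imputation, mRMR feature
selection, SMOTE class balancing and random-search hyperparameter
optimization; six classifier families are trained per fold and scored on
the untouched test rows with ACC / SNS / SPC / PPV / NPV / AUC (one-vs-rest
macro-averaged for the three-class task).  Fold metrics are aggregated as
means with percentile 95% confidence intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ..exceptions import (
    BBBPermError,
    ConfigurationError,
    HPOError,
    UndefinedMetricError,
)
from ..features import FeatureTable
from .models import ModelSpec, MODEL_FAMILIES, make_estimator, sample_params
from .preprocess import (
    MRMRSelector,
    SMOTEOversampler,
    StandardizerState,
    fit_apply_standardizer,
    knn_impute,
)

__all__ = [
    "SplitPlan",
    "monte_carlo_splits",
    "MetricSet",
    "evaluate",
    "random_search",
    "PreprocState",
    "preprocess_fold",
    "CVConfig",
    "CVReport",
    "run_cv",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "sns", "spc", "ppv", "npv", "auc")


# ---------------------------------------------------------------------------
# Splits


@dataclass(frozen=True)
class SplitPlan:
    """Independent random train/test splits (Monte Carlo CV)."""

    n_rows: int
    n_folds: int
    test_fraction: float
    seed: int
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]


def monte_carlo_splits(
    n_rows: int, n_folds: int = 100, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Draw ``n_folds`` unstratified random splits with
    ``round(test_fraction * n_rows)`` test rows each."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must be in (0, 1)")
    if n_rows < 5:
        raise ConfigurationError("need at least 5 rows")
    n_test = int(round(test_fraction * n_rows))
    n_test = min(max(n_test, 1), n_rows - 1)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        perm = rng.permutation(n_rows)
        folds.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
    return SplitPlan(
        n_rows=n_rows,
        n_folds=n_folds,
        test_fraction=test_fraction,
        seed=seed,
        folds=tuple(folds),
    )


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricSet:
    """ACC / SNS / SPC / PPV / NPV / AUC, each in [0, 1]."""

    acc: float
    sns: float
    spc: float
    ppv: float
    npv: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, ...]:
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    return (
        ratio(tp + tn, tp + tn + fp + fn),
        ratio(tp, tp + fn),  # sensitivity
        ratio(tn, tn + fp),  # specificity
        ratio(tp, tp + fp),  # PPV
        ratio(tn, tn + fn),  # NPV
    )


def evaluate(
    y_true: np.ndarray,
    proba: np.ndarray,
    classes: np.ndarray,
    task: str = "two_class",
    positive_class=None,
) -> MetricSet:
    """Score class-probability predictions.

    Two-class: confusion metrics at the 0.5 probability cutoff on the
    positive class plus ROC AUC (midrank tie handling).  Multiclass:
    per-class one-vs-rest metrics with predicted label = argmax
    probability, macro-averaged; AUC is the macro mean of the per-class
    one-vs-rest AUCs.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    classes = np.asarray(classes)
    if proba.ndim != 2 or proba.shape[1] != len(classes):
        raise ValueError("proba must be (n_samples, n_classes)")
    present = np.unique(y_true)
    if len(present) < 2:
        raise UndefinedMetricError("AUC undefined: single-class ground truth")
    if task == "two_class":
        if len(classes) != 2:
            raise ValueError("two_class task needs exactly 2 classes")
        if positive_class is None:
            positive_class = classes[1]
        pos_idx = int(np.nonzero(classes == positive_class)[0][0])
        p_pos = proba[:, pos_idx]
        truth = y_true == positive_class
        pred = p_pos >= 0.5
        acc, sns, spc, ppv, npv = _confusion_metrics(truth, pred)
        auc = float(roc_auc_score(truth, p_pos))
        return MetricSet(acc, sns, spc, ppv, npv, auc)
    if task != "multiclass":
        raise ConfigurationError(f"unknown task {task!r}")
    pred_label = classes[np.argmax(proba, axis=1)]
    per_class = []
    aucs = []
    for idx, cls in enumerate(classes):
        truth = y_true == cls
        pred = pred_label == cls
        per_class.append(_confusion_metrics(truth, pred))
        if truth.any() and (~truth).any():
            aucs.append(float(roc_auc_score(truth, proba[:, idx])))
    macro = np.mean(per_class, axis=0)
    return MetricSet(*macro, float(np.mean(aucs)))


# ---------------------------------------------------------------------------
# Hyperparameter optimization


def random_search(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    inner_fraction: float = 0.2,
) -> tuple[dict, float]:
    """Random-search HPO scored by macro AUC on an inner 80/20 split of the
    training data.  Deterministic given ``spec.seed``; returns
    ``(best_params, best_inner_auc)``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(spec.seed)
    # inner split must contain every class in both halves; retry a few draws
    n_val = max(int(round(inner_fraction * len(y))), 1)
    for _ in range(100):
        perm = rng.permutation(len(y))
        tr, va = perm[n_val:], perm[:n_val]
        if len(np.unique(y[tr])) == len(np.unique(y)) and len(np.unique(y[va])) >= 2:
            break
    else:
        raise HPOError("could not build an inner validation split covering the classes")

    task = "two_class" if len(np.unique(y)) == 2 else "multiclass"
    best_params, best_score = None, -np.inf
    for draw in range(spec.n_random_draws):
        params = sample_params(spec.space, rng)
        try:
            est = make_estimator(spec.family, params, seed=spec.seed + draw)
            est.fit(X[tr], y[tr])
            proba = est.predict_proba(X[va])
            score = evaluate(y[va], proba, est.classes_, task=task).auc
        except (BBBPermError, ValueError, np.linalg.LinAlgError) as exc:
            logger.debug("HPO draw %d (%s) failed: %s", draw, spec.family, exc)
            continue
        if score > best_score:
            best_params, best_score = params, score
    if best_params is None:
        raise HPOError(f"all {spec.n_random_draws} candidates failed for {spec.family}")
    return best_params, float(best_score)


# ---------------------------------------------------------------------------
# Fold preprocessing


@dataclass
class PreprocState:
    """Everything fitted on the training rows of one fold."""

    standardizer: StandardizerState
    selected_features: list[str]
    fitted_on_train: bool = True


def preprocess_fold(
    X_train: pd.DataFrame,
    X_test: pd.DataFrame,
    y_train: np.ndarray,
    n_select: int,
    impute_k: int = 5,
) -> tuple[np.ndarray, np.ndarray, PreprocState]:
    """Standardize -> kNN-impute -> mRMR, all fitted on train only."""
    columns = list(X_train.columns)
    Xtr, Xte, std_state = fit_apply_standardizer(
        X_train.to_numpy(float), X_test.to_numpy(float)
    )
    if np.isnan(Xtr).any() or np.isnan(Xte).any():
        # impute test rows against the training pool so no test statistic
        # leaks into the fitted state
        n_train = len(Xtr)
        Xtr = knn_impute(Xtr, k=impute_k)
        stacked = np.vstack([Xtr, Xte])
        completed = knn_impute(stacked, k=impute_k)
        Xte = completed[n_train:]
    selector = MRMRSelector(n_features_to_select=n_select).fit(Xtr, y_train)
    state = PreprocState(
        standardizer=std_state,
        selected_features=[columns[j] for j in selector.ranking_],
    )
    return selector.transform(Xtr), selector.transform(Xte), state


# ---------------------------------------------------------------------------
# The full pipeline


@dataclass
class CVConfig:
    """Configuration of the Monte Carlo CV run.

    ``task`` is ``two_class`` (CNS+ vs CNS−) or ``multiclass`` (keeps the
    efflux label).  ``efflux_policy`` applies to the two-class task:
    ``drop`` removes efflux rows, ``merge`` relabels them CNS-positive
    (efflux substrates are passively permeable).
    """

    task: str = "two_class"
    n_folds: int = 100
    test_fraction: float = 0.2
    models: tuple[str, ...] = tuple(MODEL_FAMILIES)
    n_select: int = 10
    n_random_draws: int = 25
    impute_k: int = 5
    smote: bool = True
    smote_k: int = 5
    efflux_policy: str = "drop"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("two_class", "multiclass"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.efflux_policy not in ("drop", "merge"):
            raise ConfigurationError(f"unknown efflux_policy {self.efflux_policy!r}")
        unknown = set(self.models) - set(MODEL_FAMILIES)
        if unknown:
            raise ConfigurationError(f"unknown model families: {sorted(unknown)}")


@dataclass
class CVReport:
    """Per-fold metric records plus mean / percentile-95%-CI summaries."""

    task: str
    n_folds: int
    per_fold: dict[str, list[MetricSet]]
    chosen_params: dict[str, list[dict]] = field(default_factory=dict)

    def summary(self) -> dict:
        out: dict = {}
        for model, records in self.per_fold.items():
            out[model] = {}
            for metric in METRIC_NAMES:
                vals = np.array([getattr(r, metric) for r in records], dtype=float)
                lo, hi = np.percentile(vals, [2.5, 97.5])
                out[model][metric] = {
                    "mean": float(vals.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "per_fold": vals.tolist(),
                }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"task": self.task, "models": self.summary()}, indent=2))


def _build_target(table: FeatureTable, config: CVConfig) -> tuple[pd.DataFrame, np.ndarray]:
    df = table.data
    y = table.labels.to_numpy()
    if config.task == "two_class":
        if config.efflux_policy == "drop":
            keep = y != "efflux"
            df, y = df.loc[keep], y[keep]
        else:
            y = np.where(y == "efflux", "cns_pos", y)
    return df[table.feature_columns], np.asarray(y)


def run_cv(table: FeatureTable, config: CVConfig | None = None) -> CVReport:
    """Run the full Monte Carlo CV pipeline on a feature table.

    Per fold: split -> standardize (train-fit) -> kNN-impute -> mRMR ->
    SMOTE (train only) -> random-search HPO -> fit each family -> evaluate
    on the untouched test rows.
    """
    config = config or CVConfig()
    X_all, y_all = _build_target(table, config)
    plan = monte_carlo_splits(
        len(X_all), config.n_folds, config.test_fraction, seed=config.seed
    )
    per_fold: dict[str, list[MetricSet]] = {m: [] for m in config.models}
    chosen: dict[str, list[dict]] = {m: [] for m in config.models}
    for fold_idx, (train_idx, test_idx) in enumerate(plan.folds):
        fold_seed = config.seed + fold_idx
        y_train, y_test = y_all[train_idx], y_all[test_idx]
        try:
            Xtr, Xte, _state = preprocess_fold(
                X_all.iloc[train_idx],
                X_all.iloc[test_idx],
                y_train,
                n_select=config.n_select,
                impute_k=config.impute_k,
            )
            if config.smote:
                Xtr, y_train = SMOTEOversampler(
                    k_neighbors=config.smote_k, random_state=fold_seed
                ).fit_resample(Xtr, y_train)
            for model in config.models:
                spec = ModelSpec(
                    family=model,
                    n_random_draws=config.n_random_draws,
                    seed=fold_seed,
                )
                params, inner_auc = random_search(spec, Xtr, y_train)
                est = make_estimator(model, params, seed=fold_seed)
                est.fit(Xtr, y_train)
                proba = est.predict_proba(Xte)
                metrics = evaluate(
                    y_test,
                    proba,
                    est.classes_,
                    task=config.task,
                    positive_class="cns_pos" if "cns_pos" in y_test else None,
                )
                per_fold[model].append(metrics)
                chosen[model].append(params)
                logger.info(
                    "fold %d %s: auc=%.3f acc=%.3f (inner auc %.3f)",
                    fold_idx, model, metrics.auc, metrics.acc, inner_auc,
                )
        except BBBPermError as exc:
            raise type(exc)(f"fold {fold_idx}: {exc}") from exc
    return CVReport(
        task=config.task, n_folds=config.n_folds, per_fold=per_fold, chosen_params=chosen
    )
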