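"""Monte Carlo CV machinery: splits, preprocessing, mRMR, SMOTE, HPO, metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from bbbperm import synthdata
from bbbperm.exceptions import (
    ConfigurationError,
    ImputationError,
    ResamplingError,
    UndefinedMetricError,
)
from bbbperm.features import FeatureTable
from bbbperm.mlcv import (
    CVConfig,
    EBMClassifier,
    MRMRSelector,
    ModelSpec,
    SMOTEOversampler,
    evaluate,
    fit_apply_standardizer,
    knn_impute,
    monte_carlo_splits,
    preprocess_fold,
    random_search,
    run_cv,
)


class TestSplits:
    def test_fold_sizes_154(self):
        plan = monte_carlo_splits(154, n_folds=10, test_fraction=0.2, seed=0)
        for train, test in plan.folds:
            assert len(test) == 31
            assert len(train) == 123

    def test_partition_property(self):
        plan = monte_carlo_splits(50, n_folds=20, seed=3)
        for train, test in plan.folds:
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 50

    def test_seed_determinism_and_sensitivity(self):
        a = monte_carlo_splits(40, n_folds=5, seed=1)
        b = monte_carlo_splits(40, n_folds=5, seed=1)
        c = monte_carlo_splits(40, n_folds=5, seed=2)
        assert all(np.array_equal(x[1], y[1]) for x, y in zip(a.folds, b.folds))
        assert any(not np.array_equal(x[1], y[1]) for x, y in zip(a.folds, c.folds))

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            monte_carlo_splits(50, test_fraction=1.5)


class TestStandardizer:
    def test_train_moments(self, rng):
        X = rng.normal(5, 3, (40, 4))
        Xs, _, _ = fit_apply_standardizer(X)
        assert np.abs(Xs.mean(axis=0)).max() < 1e-9
        assert np.abs(Xs.std(axis=0) - 1).max() < 1e-9

    def test_constant_column_centered_not_scaled(self):
        X = np.column_stack([np.full(10, 7.0), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Xs, _, state = fit_apply_standardizer(X)
        assert np.allclose(Xs[:, 0], 0.0)
        assert state.sd[0] == 1.0

    def test_test_rows_use_train_statistics(self, rng):
        train = rng.normal(0, 1, (30, 2))
        test = rng.normal(10, 5, (10, 2))
        _, test_s, _ = fit_apply_standardizer(train, test)
        own_z = (test - test.mean(0)) / test.std(0)
        assert not np.allclose(test_s, own_z)


class TestKnnImpute:
    def test_identical_neighbors_value(self):
        X = np.array([[1.0, 5.0]] * 6 + [[1.0, np.nan]])
        out = knn_impute(X, k=5)
        assert out[-1, 1] == pytest.approx(5.0)

    def test_k1_nearest_row(self):
        X = np.array([[0.0, 1.0], [0.1, np.nan], [10.0, 99.0]])
        out = knn_impute(X, k=1)
        assert out[1, 1] == pytest.approx(1.0)

    def test_complete_matrix_unchanged(self, rng):
        X = rng.normal(size=(12, 3))
        assert np.array_equal(knn_impute(X), X)

    def test_all_missing_row_rejected(self):
        with pytest.raises(ImputationError):
            knn_impute(np.array([[1.0, 2.0], [np.nan, np.nan]]))


def _brute_force_mrmr(X, y, n_select):
    """Independent greedy mRMR: F-statistic relevance, |Pearson| redundancy,
    quotient objective, plain loops."""
    n_features = X.shape[1]
    classes = np.unique(y)

    def relevance(j):
        groups = [X[y == c, j] for c in classes]
        if any(np.std(g) == 0 for g in groups) and np.std(X[:, j]) == 0:
            return 0.0
        f = stats.f_oneway(*groups).statistic
        return float(f) if np.isfinite(f) else 0.0

    def abs_corr(i, j):
        if np.std(X[:, i]) == 0 or np.std(X[:, j]) == 0:
            return 0.0
        return abs(float(np.corrcoef(X[:, i], X[:, j])[0, 1]))

    rel = [relevance(j) for j in range(n_features)]
    selected = [int(np.argmax(rel))]
    while len(selected) < n_select:
        best, best_score = None, -np.inf
        for j in range(n_features):
            if j in selected:
                continue
            red = np.mean([abs_corr(j, s) for s in selected])
            score = rel[j] / max(red, 1e-12)
            if score > best_score:
                best, best_score = j, score
        selected.append(best)
    return selected


class TestMRMR:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 6
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, p))
        X[:, 0] += 1.5 * y  # relevant
        X[:, 1] = X[:, 0] + rng.normal(0, 0.05, n)  # redundant copy
        sel = MRMRSelector(n_features_to_select=p).fit(X, y)
        assert sel.ranking_ == _brute_force_mrmr(X, y, p)

    def test_separating_feature_first_and_duplicate_penalized(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        signal_a = y + rng.normal(0, 0.3, n)
        signal_b = y + rng.normal(0, 0.3, n)  # equally informative twin
        X = np.column_stack([rng.normal(size=(n, 2)), signal_a, signal_b, signal_a.copy()])
        sel = MRMRSelector(n_features_to_select=5).fit(X, y)
        # one informative signal is picked first; the exact duplicate
        # (redundancy 1) loses the second slot to the independent twin
        # (redundant only through the class signal, |r| ~ 0.7)
        assert set(sel.ranking_[:2]) == {2, 3}
        assert 4 not in sel.ranking_[:2]

    def test_select_all_returns_all(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        sel = MRMRSelector(n_features_to_select=4).fit(X, y)
        assert sorted(sel.ranking_) == [0, 1, 2, 3]

    def test_constant_feature_ranked_last(self, rng):
        n = 50
        y = rng.integers(0, 2, n)
        X = np.column_stack([np.full(n, 3.0), y + rng.normal(0, 0.5, n), rng.normal(size=n)])
        sel = MRMRSelector(n_features_to_select=3).fit(X, y)
        assert sel.ranking_[-1] == 0


class TestSMOTE:
    def test_count_conservation(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.array(["A"] * 40 + ["B"] * 10)
        Xr, yr = SMOTEOversampler(random_state=0).fit_resample(X, y)
        assert dict(zip(*np.unique(yr, return_counts=True))) == {"A": 40, "B": 40}
        # originals retained verbatim, first
        assert np.array_equal(Xr[:50], X)

    def test_synthetic_points_are_convex_combinations(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array(["A"] * 24 + ["B"] * 6)
        Xr, yr = SMOTEOversampler(random_state=1).fit_resample(X, y)
        originals = X[y == "B"]
        for s in Xr[30:]:
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    d = originals[j] - originals[i]
                    t = np.dot(s - originals[i], d) / np.dot(d, d)
                    if 0 <= t <= 1 and np.allclose(originals[i] + t * d, s, atol=1e-9):
                        on_segment = True
            assert on_segment

    def test_identical_members_duplicate(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((9, 2))])
        y = np.array(["B"] * 3 + ["A"] * 9)
        Xr, yr = SMOTEOversampler(random_state=2).fit_resample(X, y)
        assert np.array_equal(Xr[yr == "B"], np.zeros((9, 2)))

    def test_singleton_class_rejected(self):
        X = np.arange(10.0).reshape(5, 2)
        y = np.array(["A", "A", "A", "A", "B"])
        with pytest.raises(ResamplingError):
            SMOTEOversampler().fit_resample(X, y)


class TestRandomSearch:
    def _toy(self, rng, n=60):
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.normal(size=(n, 2))
        X[:, 0] += 5 * y
        return X, y

    def test_single_point_space(self, rng):
        X, y = self._toy(rng)
        spec = ModelSpec("knn", space={"n_neighbors": [3]}, n_random_draws=4, seed=0)
        params, _ = random_search(spec, X, y)
        assert params == {"n_neighbors": 3}

    def test_seed_determinism(self, rng):
        X, y = self._toy(rng)
        spec = ModelSpec("random_forest", n_random_draws=4, seed=7)
        assert random_search(spec, X, y) == random_search(spec, X, y)

    def test_separable_toy_reaches_inner_auc_one(self, rng):
        X, y = self._toy(rng)
        spec = ModelSpec("logistic_regression", n_random_draws=5, seed=1)
        _, inner_auc = random_search(spec, X, y)
        assert inner_auc == pytest.approx(1.0)


class TestEvaluate:
    def test_perfect_two_class(self):
        y = np.array([0, 0, 1, 1])
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        m = evaluate(y, proba, classes=np.array([0, 1]), task="two_class")
        assert (m.acc, m.sns, m.spc, m.ppv, m.npv, m.auc) == (1, 1, 1, 1, 1, 1)

    def test_uninformative_scores_auc_half(self):
        y = np.array([0, 1, 0, 1, 1])
        proba = np.full((5, 2), 0.5)
        m = evaluate(y, proba, classes=np.array([0, 1]), task="two_class")
        assert m.auc == pytest.approx(0.5)

    def test_hand_computed_confusion(self):
        # predictions at 0.5: [1, 1, 0, 0, 1]; truth [1, 0, 0, 1, 1]
        y = np.array([1, 0, 0, 1, 1])
        p1 = np.array([0.7, 0.6, 0.2, 0.4, 0.9])
        m = evaluate(y, np.column_stack([1 - p1, p1]), classes=np.array([0, 1]))
        assert m.acc == pytest.approx(3 / 5)
        assert m.sns == pytest.approx(2 / 3)
        assert m.spc == pytest.approx(1 / 2)
        assert m.ppv == pytest.approx(2 / 3)
        assert m.npv == pytest.approx(1 / 2)

    def test_macro_auc_is_mean_of_one_vs_rest(self):
        y = np.array(["a", "a", "b", "b", "c", "c"])
        proba = np.array(
            [
                [0.8, 0.1, 0.1], [0.7, 0.2, 0.1],  # a separated
                [0.1, 0.3, 0.6], [0.2, 0.3, 0.5],  # b and c swapped
                [0.1, 0.6, 0.3], [0.2, 0.5, 0.3],
            ]
        )
        m = evaluate(y, proba, classes=np.array(["a", "b", "c"]), task="multiclass")
        from sklearn.metrics import roc_auc_score

        expected = np.mean([roc_auc_score(y == c, proba[:, i]) for i, c in enumerate("abc")])
        assert m.auc == pytest.approx(expected)
        # by hand: class a fully separated (AUC 1); b and c each rank above
        # half the rest (AUC 0.5): macro = (1 + 0.5 + 0.5)/3
        assert m.auc == pytest.approx(2 / 3)

    def test_single_class_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            evaluate(np.zeros(4, int), np.full((4, 2), 0.5), classes=np.array([0, 1]))


class TestEBM:
    def test_sklearn_protocol(self):
        est = EBMClassifier(n_cycles=5)
        assert clone(est).get_params()["n_cycles"] == 5

    def test_learns_additive_signal(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + np.sin(2 * X[:, 1]) > 0).astype(int)
        est = EBMClassifier(n_cycles=30, random_state=0).fit(X, y)
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (est.predict(X) == y).mean() > 0.9

    def test_multiclass_probabilities(self, rng):
        X = rng.normal(size=(90, 2))
        y = np.repeat([0, 1, 2], 30)
        X[:, 0] += 3 * y
        est = EBMClassifier(n_cycles=15, random_state=0).fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (90, 3)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (est.predict(X) == y).mean() > 0.9

    def test_ignored_feature_has_flat_shape(self, rng):
        X = rng.normal(size=(150, 2))
        y = (X[:, 0] > 0).astype(int)
        X[:, 1] = 0.0  # constant: carries no signal
        est = EBMClassifier(n_cycles=10, random_state=0).fit(X, y)
        grid = np.linspace(-2, 2, 9)
        assert np.allclose(est.shape_function(1, grid), est.shape_function(1, grid)[0])


class TestPipeline:
    def test_no_leakage_from_test_rows(self, default_table, rng):
        X = default_table.features
        y = default_table.labels.to_numpy()
        train, test = np.arange(100), np.arange(100, 154)
        Xtr1, _, state1 = preprocess_fold(X.iloc[train], X.iloc[test], y[train], n_select=8)
        perturbed = X.iloc[test] + rng.normal(0, 10, X.iloc[test].shape)
        Xtr2, _, state2 = preprocess_fold(X.iloc[train], perturbed, y[train], n_select=8)
        assert np.array_equal(state1.standardizer.mean, state2.standardizer.mean)
        assert state1.selected_features == state2.selected_features
        assert np.array_equal(Xtr1, Xtr2)

    def test_runs_end_to_end_on_imbalanced_classes(self):
        table = synthdata.generate_feature_table(seed=9)
        config = CVConfig(
            task="multiclass", n_folds=2, models=("logistic_regression",),
            n_random_draws=2, seed=0,
        )
        report = run_cv(table, config)
        assert len(report.per_fold["logistic_regression"]) == 2
        for metric, agg in report.summary()["logistic_regression"].items():
            assert agg["ci_low"] <= agg["mean"] <= agg["ci_high"]

    def test_two_class_efflux_policies(self):
        table = synthdata.generate_feature_table(seed=9)
        for policy in ("drop", "merge"):
            config = CVConfig(
                task="two_class", n_folds=1, models=("knn",), n_random_draws=2,
                efflux_policy=policy, seed=0,
            )
            report = run_cv(table, config)
            assert 0.0 <= report.per_fold["knn"][0].auc <= 1.0

    def test_missing_values_are_imputed_in_pipeline(self):
        table = synthdata.generate_feature_table(
            synthdata.default_config(missing_rate=0.05), seed=2
        )
        config = CVConfig(
            task="two_class", n_folds=1, models=("logistic_regression",),
            n_random_draws=2, seed=1,
        )
        report = run_cv(table, config)
        assert np.isfinite(report.per_fold["logistic_regression"][0].auc)
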