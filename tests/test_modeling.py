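"""Preprocessing, SMOTE, reducers, repeated CV, DeLong and importance."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petrad.modeling import (SkewnessLogTransformer, compare_models,
                             delong_test, feature_importance, fit_reducer,
                             log_transform_skewed, oversample_smote,
                             run_repeated_cv)
from petrad.selection import FeatureTable, ModelSpec


def _table(X, y, approach="reference"):
    X = pd.DataFrame(np.asarray(X, float),
                     columns=[f"f{k}" for k in range(np.asarray(X).shape[1])])
    return FeatureTable(list(range(len(X))), X, np.asarray(y, int), approach)


class TestLogTransform:
    def test_symmetric_column_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, (500, 1))
        tr = SkewnessLogTransformer().fit(x)
        assert not tr.transform_mask_[0]
        assert np.array_equal(tr.transform(x), x)

    def test_lognormal_column_transformed_to_near_symmetry(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(size=(10_000, 1)))
        tr = SkewnessLogTransformer().fit(x)
        assert tr.transform_mask_[0]
        assert abs(stats.skew(tr.transform(x)[:, 0])) < 0.1

    def test_skewed_column_with_zero_left_alone(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(size=(500, 1)))
        x[0, 0] = 0.0
        tr = SkewnessLogTransformer().fit(x)
        assert not tr.transform_mask_[0]

    def test_table_wrapper_preserves_shape(self):
        rng = np.random.default_rng(3)
        t = _table(np.exp(rng.normal(size=(60, 4))), rng.integers(0, 2, 60))
        t2 = log_transform_skewed(t)
        assert t2.X.shape == t.X.shape
        assert list(t2.X.columns) == list(t.X.columns)


class TestReducers:
    def test_anova_top10pct_keeps_48_of_480(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 480))
        y = rng.integers(0, 2, 100)
        red = fit_reducer("anova_top10pct", X, y)
        assert red.transform(X).shape[1] == 48

    def test_pca_on_two_orthogonal_features(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.normal(size=200), rng.normal(size=200)])
        y = rng.integers(0, 2, 200)
        red = fit_reducer("pca", X, y)
        Z = red.transform(X)
        pca = red.reducer
        assert pca.explained_variance_ratio_.sum() >= 0.95
        back = pca.inverse_transform(Z)
        assert np.allclose(back + pca.mean_ * 0, back)  # shape sanity
        assert Z.shape[0] == 200

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        X[:, 1] = 7.0
        y = rng.integers(0, 2, 50)
        with pytest.warns(UserWarning, match="constant"):
            red = fit_reducer("none", X, y)
        assert red.transform(X).shape[1] == 2

    def test_rfe_rf_recovers_determining_feature(self):
        """One feature fully determines y among 19 noise features: RFE with a
        random-forest ranker must retain it in >= 95% of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 20))
            y = (X[:, 7] > 0).astype(int)
            if len(np.unique(y)) < 2:
                hits += 1
                continue
            red = fit_reducer("rfe_rf", X, y, seed=seed, rfe_n_estimators=50)
            if red.reducer.get_support()[7]:
                hits += 1
        assert hits >= 95

    @pytest.mark.parametrize("method", ["rfe_svm", "rfe_lr", "fa"])
    def test_other_reducers_transform_unseen_rows(self, method):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 30))
        y = rng.integers(0, 2, 80)
        red = fit_reducer(method, X, y, seed=0)
        Z = red.transform(rng.normal(size=(5, 30)))
        assert Z.shape[0] == 5 and np.isfinite(Z).all()


class TestSmote:
    def test_balances_to_majority_count(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3))
        y = np.r_[np.ones(10), np.zeros(40)].astype(int)
        X2, y2 = oversample_smote(X, y, seed=0)
        assert np.bincount(y2).tolist() == [40, 40]
        assert np.array_equal(X2[:50], X)

    def test_identical_minority_points_reproduce_themselves(self):
        X = np.vstack([np.tile([1.0, 2.0], (5, 1)),
                       np.random.default_rng(0).normal(size=(20, 2))])
        y = np.r_[np.ones(5), np.zeros(20)].astype(int)
        X2, y2 = oversample_smote(X, y, seed=1)
        assert np.allclose(X2[25:], [1.0, 2.0])

    def test_synthetic_points_stay_on_segment(self):
        # minority on a line: synthetic rows must stay on that line
        t = np.linspace(0, 1, 8)
        Xm = np.column_stack([t, 2 * t + 1])
        X = np.vstack([Xm, np.random.default_rng(1).normal(10, 1, (30, 2))])
        y = np.r_[np.ones(8), np.zeros(30)].astype(int)
        X2, _ = oversample_smote(X, y, seed=2)
        new = X2[38:]
        assert np.allclose(new[:, 1], 2 * new[:, 0] + 1, atol=1e-9)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            oversample_smote(np.ones((5, 2)), np.ones(5, int))


class TestRepeatedCv:
    def test_null_features_give_chance_auc(self):
        rng = np.random.default_rng(10)
        t = _table(rng.normal(size=(100, 8)), rng.integers(0, 2, 100))
        res = run_repeated_cv(t, ModelSpec("reference"), n_repeats=10, seed=0)
        assert 0.45 <= res.mean_auc <= 0.55

    def test_separable_feature_gives_high_auc(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([y + rng.normal(0, 0.01, 100), rng.normal(size=100)])
        res = run_repeated_cv(_table(X, y), ModelSpec("reference"),
                              n_repeats=5, seed=0)
        assert res.mean_auc >= 0.99

    def test_determinism_and_shape(self):
        rng = np.random.default_rng(12)
        t = _table(rng.normal(size=(60, 5)), rng.integers(0, 2, 60))
        r1 = run_repeated_cv(t, ModelSpec("reference", "interpolate"), n_repeats=3, seed=5)
        r2 = run_repeated_cv(t, ModelSpec("reference", "interpolate"), n_repeats=3, seed=5)
        assert np.array_equal(r1.aucs, r2.aucs)
        assert r1.aucs.shape == (3, 5)
        assert np.all((r1.aucs >= 0) & (r1.aucs <= 1))

    def test_leakage_canary_small(self):
        """An outcome-correlated feature present only in test rows must not
        move the CV-AUC of a leak-free pipeline."""
        rng = np.random.default_rng(13)
        n = 120
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 4))
        # canary slot: constant in the stored table, so any training-side step
        # must discard it; the mutator makes it outcome-valued in test rows
        X = np.column_stack([X, np.zeros(n)])
        t = _table(X, y)

        def mutator(X_te, te):
            X_te[:, -1] = y[te]
            return X_te

        with pytest.warns(UserWarning, match="constant"):
            base = run_repeated_cv(t, ModelSpec("reference"), n_repeats=5, seed=3)
            canary = run_repeated_cv(t, ModelSpec("reference"), n_repeats=5, seed=3,
                                     test_row_mutator=mutator)
        assert abs(canary.mean_auc - base.mean_auc) < 0.01


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        p, a, b = delong_test([.1, .2, .8, .9], [.1, .2, .8, .9], [0, 0, 1, 1])
        assert p == 1.0 and a == 1.0 and b == 1.0

    def test_opposed_rankings(self):
        p, a, b = delong_test([.1, .2, .8, .9], [.9, .8, .2, .1], [0, 0, 1, 1])
        assert a == 1.0 and b == 0.0

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            delong_test([.1, .2], [.3, .4], [1, 1])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(14)
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        ps = [delong_test(rng.normal(size=100), rng.normal(size=100), y)[0]
              for _ in range(500)]
        assert abs(np.mean(np.asarray(ps) < 0.5) - 0.5) < 0.08
        assert abs(np.mean(np.asarray(ps) < 0.05) - 0.05) < 0.03


class TestCompareModels:
    def test_same_model_gives_median_p_one(self):
        rng = np.random.default_rng(15)
        t = _table(rng.normal(size=(60, 4)), rng.integers(0, 2, 60))
        res = compare_models(t, ModelSpec("reference"), t, ModelSpec("reference"),
                             n_repeats=2, seed=1)
        assert res.median_p == 1.0

    def test_informative_vs_null_detected(self):
        rng = np.random.default_rng(16)
        y = rng.integers(0, 2, 120)
        informative = _table(np.column_stack([y + rng.normal(0, 0.3, 120),
                                              rng.normal(size=120)]), y)
        null = _table(rng.normal(size=(120, 2)), y)
        res = compare_models(informative, ModelSpec("reference"),
                             null, ModelSpec("reference"), n_repeats=4, seed=2)
        assert res.median_p < 0.05
        assert res.mean_auc_a > res.mean_auc_b

    def test_mismatched_patients_error(self):
        rng = np.random.default_rng(17)
        t1 = _table(rng.normal(size=(20, 2)), rng.integers(0, 2, 20))
        t2 = FeatureTable(list(range(100, 120)), t1.X, t1.y)
        with pytest.raises(ValueError, match="same patients"):
            compare_models(t1, ModelSpec("reference"), t2, ModelSpec("reference"))


class TestImportance:
    def test_sums_to_one_and_finds_signal(self):
        rng = np.random.default_rng(18)
        y = rng.integers(0, 2, 150)
        X = rng.normal(size=(150, 11))
        X[:, 4] = y + rng.normal(0, 0.2, 150)
        t = _table(X, y)
        imp = feature_importance(t, ModelSpec("reference"), seed=0, n_estimators=200)
        assert imp.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.top(1)[0][0] == "f4"

    def test_single_feature_gets_all_importance(self):
        rng = np.random.default_rng(19)
        y = rng.integers(0, 2, 60)
        t = _table(rng.normal(size=(60, 1)), y)
        imp = feature_importance(t, ModelSpec("reference"), n_estimators=50)
        assert imp.importances.tolist() == [1.0]

    def test_pca_rejected(self):
        rng = np.random.default_rng(20)
        t = _table(rng.normal(size=(40, 5)), rng.integers(0, 2, 40))
        with pytest.raises(ValueError, match="interpretable"):
            feature_importance(t, ModelSpec("reference", reduction="pca"))
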