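"""Risk-factor pipeline: contrast assembly, preprocessing, model, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sdqtransitions.riskfactors import (
    ModelConfig,
    TransitionContrast,
    build_contrast,
    filter_missingness,
    gain_importance,
    genuine_risk_factors,
    identify_risk_factors,
    impute_knn,
    permutation_survival,
    scale_minmax,
    select_by_threshold,
    split_train_test,
    tune_model,
    _classifier,
)

SINGLETON_GRID = {
    "n_estimators": [100],
    "learning_rate": [0.3],
    "max_depth": [3],
    "min_child_weight": [1],
    "gamma": [0.0],
    "reg_alpha": [1.0],
}


def fast_config(seed=0, **kwargs):
    return ModelConfig(grid=dict(SINGLETON_GRID), permutation_repeats=10, seed=seed, **kwargs)


def linked_frame(n_pos, n_neg, n_other=0):
    n = n_pos + n_neg + n_other
    dest = ["D"] * n_pos + ["non_elevated"] * n_neg + ["other"] * n_other
    return pd.DataFrame(
        {"child_id": np.arange(n), "group_source": "S", "group_dest": dest}
    )


class TestBuildContrast:
    def test_planted_split_counts(self):
        contrast = build_contrast(linked_frame(30, 70), "S", "D", "non_elevated")
        assert contrast.outcomes.sum() == 30
        assert len(contrast.outcomes) == 100

    def test_third_destination_excluded(self):
        contrast = build_contrast(linked_frame(30, 70, n_other=25), "S", "D", "non_elevated")
        assert len(contrast.child_ids) == 100

    def test_empty_positive_class_is_an_error(self):
        with pytest.raises(ValueError, match="interest"):
            build_contrast(linked_frame(0, 50), "S", "D", "non_elevated")


class TestPreprocessing:
    def test_missingness_filter_boundary(self):
        cov = pd.DataFrame(
            {"child_id": [0, 1, 2]}
            | {
                f"f{i}": [
                    np.nan if i < 4 else 1.0,   # child 0: 40% missing -> excluded
                    np.nan if i < 3 else 1.0,   # child 1: exactly 30% -> retained
                    1.0,                        # child 2: complete -> retained
                ]
                for i in range(10)
            }
        )
        kept = filter_missingness(cov, threshold=0.30)
        assert list(kept["child_id"]) == [1, 2]

    def test_split_sizes_and_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = np.array([1] * 40 + [0] * 60)
        tr1, te1, ytr1, yte1 = split_train_test(X, y, 0.2, seed=3)
        tr2, te2, _, _ = split_train_test(X, y, 0.2, seed=3)
        assert len(tr1) == 80 and len(te1) == 20
        pd.testing.assert_frame_equal(tr1, tr2)
        # stratification preserves the 40/60 ratio within rounding
        assert abs(ytr1.mean() - 0.4) < 0.02
        assert abs(yte1.mean() - 0.4) < 0.05

    def test_knn_copies_unique_nearest_neighbour(self):
        train = pd.DataFrame({"a": [0.0, 10.0], "b": [1.0, 99.0]})
        test = pd.DataFrame({"a": [0.1], "b": [np.nan]})
        _, test_imp = impute_knn(train, test, k=1)
        assert test_imp.loc[0, "b"] == 1.0

    def test_knn_identity_without_missing(self, rng):
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        test = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        tr, te = impute_knn(train, test, k=3)
        np.testing.assert_allclose(tr, train)
        np.testing.assert_allclose(te, test)

    def test_knn_beats_column_mean_on_correlated_features(self, rng):
        """MCAR 10% on correlated features: KNN RMSE < mean-imputation RMSE."""
        n = 400
        z = rng.normal(size=n)
        full = pd.DataFrame(
            {f"f{i}": z + rng.normal(0, 0.3, size=n) for i in range(4)}
        )
        masked = full.copy()
        holes = rng.random(size=(n, 4)) < 0.10
        masked = masked.mask(pd.DataFrame(holes, columns=full.columns))
        imp, _ = impute_knn(masked, masked.iloc[:5], k=5)
        knn_rmse = np.sqrt(((imp.to_numpy() - full.to_numpy())[holes] ** 2).mean())
        mean_fill = masked.fillna(masked.mean())
        mean_rmse = np.sqrt(((mean_fill.to_numpy() - full.to_numpy())[holes] ** 2).mean())
        assert knn_rmse < mean_rmse

    def test_minmax_formula_and_test_overflow(self):
        train = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        test = pd.DataFrame({"a": [8.0]})
        tr, te = scale_minmax(train, test)
        np.testing.assert_allclose(tr["a"], [0.0, 0.5, 1.0])
        assert te.loc[0, "a"] == pytest.approx(1.5)

    def test_constant_train_column_maps_to_zero_with_warning(self):
        train = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        test = pd.DataFrame({"a": [3.0]})
        with pytest.warns(UserWarning, match="constant"):
            tr, te = scale_minmax(train, test)
        assert (tr["a"] == 0).all()


def planted_data(rng, n=600, n_noise=10, coef=3.0):
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise + 1)),
        columns=[f"noise_{i}" for i in range(n_noise)] + ["signal"],
    )
    y = rng.binomial(1, expit(coef * X["signal"]))
    return X, np.asarray(y)


class TestModel:
    def test_imbalance_weight_is_inverse_class_ratio(self):
        y = np.array([1] * 10 + [0] * 90)
        model = _classifier({}, y, seed=0)
        assert model.get_params()["scale_pos_weight"] == pytest.approx(9.0)

    def test_singleton_grid_returned(self, rng):
        X, y = planted_data(rng)
        best, model, cv = tune_model(X, y, fast_config())
        assert best == {k: v[0] for k, v in SINGLETON_GRID.items()}
        assert len(cv) == 1

    def test_separable_outcome_reaches_high_accuracy(self, rng):
        X, y = planted_data(rng, coef=50.0)  # effectively a threshold rule
        X_train, X_test, y_train, y_test = split_train_test(X, y, 0.2, seed=0)
        _, model, _ = tune_model(X_train, y_train, fast_config())
        acc = (model.predict(X_test) == y_test).mean()
        assert acc >= 0.95

    def test_planted_feature_has_top_gain(self, rng):
        X, y = planted_data(rng)
        _, model, _ = tune_model(X, y, fast_config())
        gains = gain_importance(model)
        assert gains.idxmax() == "signal"

    def test_unused_feature_has_zero_gain(self, rng):
        X, y = planted_data(rng, coef=50.0)
        X["constant"] = 1.0
        _, model, _ = tune_model(X, y, fast_config())
        assert gain_importance(model)["constant"] == 0.0

    def test_null_gains_are_diffuse(self, rng):
        """Pure-noise outcome: no feature dominates the gain share."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(500, 20)), columns=[f"f{i}" for i in range(20)])
            y = r.binomial(1, 0.5, size=500)
            _, model, _ = tune_model(X, np.asarray(y), fast_config(seed=seed))
            gains = gain_importance(model)
            share = gains / gains.sum()
            if share.max() < 3 / 20:
                hits += 1
        assert hits >= 9


class TestSelectionAndPermutation:
    def test_dominant_feature_selected(self, rng):
        X, y = planted_data(rng, coef=5.0)
        X_train, X_test, y_train, y_test = split_train_test(X, y, 0.2, seed=0)
        best, model, _ = tune_model(X_train, y_train, fast_config())
        gains = gain_importance(model)
        selected, sweep = select_by_threshold(
            X_train, y_train, X_test, y_test, gains, best, seed=0
        )
        assert "signal" in selected
        assert len(sweep) <= gains[gains > 0].nunique()

    def test_all_zero_gains_select_nothing(self, rng):
        gains = pd.Series(0.0, index=list("abc"))
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="zero"):
            selected, sweep = select_by_threshold(X, y, X, y, gains, {}, seed=0)
        assert selected == []

    def test_unused_feature_has_negligible_drop(self, rng):
        X, y = planted_data(rng, n=1000, coef=50.0)
        X["dead"] = rng.normal(size=1000)
        X_train, X_test, y_train, y_test = split_train_test(X, y, 0.2, seed=0)
        best, model, _ = tune_model(X_train, y_train, fast_config())
        gains = gain_importance(model)
        perm = permutation_survival(model, X_test, y_test, gains, repeats=50, seed=0)
        if gains["dead"] == 0:
            assert abs(perm.loc["dead", "mean_drop"]) < 0.01

    def test_sole_predictor_shows_large_drop(self, rng):
        X, y = planted_data(rng, n=1000, n_noise=3, coef=50.0)
        X_train, X_test, y_train, y_test = split_train_test(X, y, 0.2, seed=0)
        best, model, _ = tune_model(X_train, y_train, fast_config())
        gains = gain_importance(model)
        perm = permutation_survival(model, X_test, y_test, gains, repeats=20, seed=0)
        assert perm.loc["signal", "mean_drop"] > 0.2

    def test_permutation_reproducible_under_fixed_seed(self, rng):
        X, y = planted_data(rng, n=300)
        X_train, X_test, y_train, y_test = split_train_test(X, y, 0.2, seed=0)
        best, model, _ = tune_model(X_train, y_train, fast_config())
        gains = gain_importance(model)
        p1 = permutation_survival(model, X_test, y_test, gains, repeats=5, seed=9)
        p2 = permutation_survival(model, X_test, y_test, gains, repeats=5, seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_genuine_is_intersection(self):
        gains = pd.Series({"a": 5.0, "b": 2.0, "c": 0.0})
        perm = pd.DataFrame(
            {"mean_drop": [0.1, -0.01, 0.0], "survives": [True, False, False]},
            index=["a", "b", "c"],
        )
        res = genuine_risk_factors(gains, ["a", "b"], perm, 0.8, 0.7, {})
        assert res.genuine == ["a"]
        table = res.table
        assert set(table.index[table["genuine"]]) <= set(table.index[table["selected"]])
        assert set(table.index[table["genuine"]]) <= set(table.index[table["survives"]])


class TestEndToEnd:
    def test_leakage_guard_transforms_independent_of_test(self, rng):
        """Imputation and scaling parameters depend on the train split only."""
        X, y = planted_data(rng, n=200)
        X_missing = X.mask(rng.random(X.shape) < 0.05)
        X_train, X_test, y_train, y_test = split_train_test(X_missing, y, 0.2, seed=0)
        tr_a, _ = impute_knn(X_train, X_test, k=3)
        tr_b, _ = impute_knn(X_train, X_test.iloc[:2] * 100, k=3)
        pd.testing.assert_frame_equal(tr_a, tr_b)
        str_a, _ = scale_minmax(tr_a, X_test.fillna(0))
        str_b, _ = scale_minmax(tr_a, X_test.fillna(0).iloc[:2] * 100)
        pd.testing.assert_frame_equal(str_a, str_b)

    def test_full_run_deterministic(self, rng):
        X, y = planted_data(rng, n=400, n_noise=6)
        X.insert(0, "child_id", np.arange(400))
        contrast = TransitionContrast("S", "D", "NE", np.arange(400), y)
        r1 = identify_risk_factors(X, contrast, fast_config(seed=5))
        r2 = identify_risk_factors(X, contrast, fast_config(seed=5))
        assert r1.genuine == r2.genuine
        pd.testing.assert_frame_equal(r1.table, r2.table)
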