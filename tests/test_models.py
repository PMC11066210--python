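import numpy as np
import pandas as pd
import pytest

from swaylab.errors import InvalidParameterError
from swaylab.models import (
    GBT_GRID,
    SVR_GRID,
    Normalizer,
    fit_mlr,
    grid_search,
    predict,
    prune_redundant,
    select_features,
    train_model,
    validate_hyperparameters,
)


def mlr_normal_equations(X, y):
    """Independent oracle: solve the normal equations directly."""
    A = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return beta


def frame(arr, prefix="f"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestNormalizer:
    def test_two_point_example(self):
        norm = Normalizer.fit(frame([[0.0], [2.0]]))
        assert norm.mean["f0"] == 1.0
        assert norm.sd["f0"] == pytest.approx(np.sqrt(2))
        assert norm.transform(frame([[1.0]]))["f0"].iloc[0] == 0.0

    def test_training_set_maps_to_zero_mean_unit_sd(self, rng):
        X = frame(rng.normal(size=(50, 4)))
        Xn = Normalizer.fit(X).transform(X)
        assert np.allclose(Xn.mean(), 0.0, atol=1e-12)
        assert np.allclose(Xn.std(ddof=1), 1.0, atol=1e-12)

    def test_constant_column_passes_through(self):
        X = frame([[2.0, 1.0], [2.0, 3.0], [2.0, 5.0]])
        Xn = Normalizer.fit(X).transform(X)
        assert np.allclose(Xn["f0"], 0.0)  # mean removed, sd treated as 1

    def test_empty_training_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            Normalizer.fit(frame(np.empty((0, 2))))


class TestSelectFeatures:
    def test_perfect_and_negated_features_selected(self, rng):
        y = rng.normal(size=40)
        X = pd.DataFrame({"pos": y, "neg": -y, "noise": rng.normal(size=40)})
        sel = select_features(X, y, threshold=0.7)
        assert sel.names == ["pos", "neg"]
        assert sel.n_above_threshold == 2

    def test_null_feature_rarely_selected(self):
        # Monte-Carlo null: |r| of independent noise at n=100 is ≪ 0.7
        rng = np.random.default_rng(42)
        y = rng.normal(size=100)
        hits = 0
        for _ in range(500):
            x = rng.normal(size=100)
            r = abs(np.corrcoef(x, y)[0, 1])
            hits += r > 0.7
        assert hits == 0  # ≥99% exclusion comfortably satisfied

    def test_empty_selection_falls_back_to_best_feature(self, rng):
        y = rng.normal(size=30)
        X = frame(rng.normal(size=(30, 5)))
        with pytest.warns(UserWarning, match="falling back"):
            sel = select_features(X, y, threshold=0.99)
        assert len(sel.names) == 1 and sel.fallback_used


class TestPruneRedundant:
    def test_duplicate_columns_keep_one(self, rng):
        y = rng.normal(size=30)
        x = y + 0.1 * rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x.copy()})
        assert len(prune_redundant(["a", "b"], X, y)) == 1

    def test_orthogonal_features_all_kept(self):
        X = pd.DataFrame(
            {"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1], "c": [1.0, -1, -1, 1]}
        )
        y = np.array([1.0, 0, 0, 1])
        assert prune_redundant(["a", "b", "c"], X, y) == ["a", "b", "c"]

    def test_correlated_cluster_keeps_strongest(self, rng):
        y = rng.normal(size=200)
        base = y + 0.05 * rng.normal(size=200)
        X = pd.DataFrame(
            {
                "strong": base,
                "weak1": base + 0.2 * rng.normal(size=200),
                "weak2": base + 0.3 * rng.normal(size=200),
            }
        )
        corr = X.corr().abs()
        assert (corr.to_numpy()[np.triu_indices(3, 1)] > 0.9).all()
        assert prune_redundant(["strong", "weak1", "weak2"], X, y) == ["strong"]


class TestMLR:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 9, 10)
        model = fit_mlr(frame(x[:, None]), 2 * x + 3)
        assert model.intercept == pytest.approx(3.0, abs=1e-10)
        assert model.coef["f0"] == pytest.approx(2.0, abs=1e-10)

    def test_constant_target(self):
        model = fit_mlr(frame(np.random.default_rng(0).normal(size=(20, 3))),
                        np.full(20, 4.2))
        assert model.intercept == pytest.approx(4.2, abs=1e-10)
        assert np.allclose(model.coef, 0.0, atol=1e-10)

    def test_known_beta_recovery(self, rng):
        X = rng.normal(size=(50, 5))
        beta = rng.normal(size=5)
        y = X @ beta + 1.5
        model = fit_mlr(frame(X), y)
        assert np.allclose(model.coef, beta, atol=1e-8)
        assert model.intercept == pytest.approx(1.5, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(30, 4))
            y = rng.normal(size=30)
            model = fit_mlr(frame(X), y)
            oracle = mlr_normal_equations(X, y)
            assert np.allclose(
                np.r_[model.intercept, model.coef], oracle, atol=1e-8
            )

    def test_residuals_orthogonal_to_design(self, rng):
        X = frame(rng.normal(size=(40, 3)))
        y = rng.normal(size=40)
        model = fit_mlr(X, y)
        resid = y - model.predict(X)
        assert np.allclose(X.to_numpy().T @ resid, 0.0, atol=1e-8)

    def test_rank_deficient_warns_and_solves(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_mlr(X, 3 * x)
        assert np.allclose(model.predict(X), 3 * x, atol=1e-8)


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        X = frame(rng.normal(size=(30, 2)))
        y = rng.normal(size=30)
        hp, _ = grid_search(X, y, "svr",
                            [{"kernel": "linear", "C": 1.0, "epsilon": 0.1}])
        assert hp == {"kernel": "linear", "C": 1.0, "epsilon": 0.1}

    def test_generating_complexity_beats_gross_underfit(self, rng):
        # noiseless linear data: a flexible linear SVR beats a tiny-C one
        X = frame(rng.normal(size=(60, 2)))
        y = 3 * X["f0"].to_numpy() - 2 * X["f1"].to_numpy()
        grid = [
            {"kernel": "linear", "C": 10.0, "epsilon": 0.01},
            {"kernel": "linear", "C": 0.1, "epsilon": 0.2},
        ]
        hp, mae = grid_search(X, y, "svr", grid, seed=1)
        assert hp["C"] == 10.0 and mae < 0.1

    def test_same_seed_same_winner(self, rng):
        X = frame(rng.normal(size=(40, 3)))
        y = rng.normal(size=40)
        grid = [dict(p) for p in SVR_GRID[:6]]
        assert grid_search(X, y, "svr", grid, seed=9) == grid_search(
            X, y, "svr", grid, seed=9
        )

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            grid_search(frame(rng.normal(size=(20, 2))),
                        rng.normal(size=20), "svr", [])


class TestBackends:
    def test_hyperparameter_ranges_enforced(self):
        with pytest.raises(InvalidParameterError):
            validate_hyperparameters(
                "svr", {"kernel": "linear", "C": 100.0, "epsilon": 0.1}
            )
        with pytest.raises(InvalidParameterError):
            validate_hyperparameters(
                "gbt", {"n_estimators": 500, "max_depth": 3,
                        "colsample_bytree": 0.3}
            )
        for hp in list(SVR_GRID):
            validate_hyperparameters("svr", hp)
        for hp in list(GBT_GRID):
            validate_hyperparameters("gbt", hp)

    def test_svr_noiseless_linear_generalizes(self, rng):
        X = frame(rng.normal(size=(80, 2)))
        y = 2 * X["f0"].to_numpy() + 0.5 * X["f1"].to_numpy() + 1
        trained = train_model(
            X.iloc[:60], y[:60], "svr",
            grid=[{"kernel": "linear", "C": 10.0, "epsilon": 0.01}],
            selection_threshold=0.0,
        )
        test_mae = np.mean(np.abs(predict(trained, X.iloc[60:]) - y[60:]))
        assert test_mae < 0.01

    def test_gbt_beats_intercept_baseline(self, rng):
        X = frame(rng.normal(size=(50, 2)))
        y = 3 * X["f0"].to_numpy()
        trained = train_model(
            X, y, "gbt",
            grid=[{"n_estimators": 10, "max_depth": 3,
                   "colsample_bytree": 0.5}],
        )
        train_mae = np.mean(np.abs(predict(trained, X) - y))
        assert train_mae < np.mean(np.abs(y - y.mean()))

    def test_gbt_deterministic_given_seed(self, rng):
        X = frame(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        grid = [{"n_estimators": 30, "max_depth": 3, "colsample_bytree": 0.3}]
        p1 = predict(train_model(X, y, "gbt", grid=grid, seed=7), X)
        p2 = predict(train_model(X, y, "gbt", grid=grid, seed=7), X)
        assert np.array_equal(p1, p2)


class TestPipelineContracts:
    def test_predict_names_missing_feature(self, rng):
        X = frame(rng.normal(size=(30, 3)))
        y = X["f0"].to_numpy()
        trained = train_model(X, y, "mlr")
        with pytest.raises(InvalidParameterError, match="f0"):
            predict(trained, X.drop(columns=["f0"]))

    def test_training_predictions_reproduce_fit(self, rng):
        X = frame(rng.normal(size=(40, 3)))
        y = 2 * X["f1"].to_numpy() + rng.normal(size=40) * 0.01
        trained = train_model(X, y, "mlr")
        fitted = trained.model.predict(
            trained.normalizer.transform(X)[trained.selected]
        )
        assert np.allclose(predict(trained, X), fitted, atol=0)

    def test_leakage_contract_held_out_rows_do_not_matter(self, rng):
        # mutate held-out rows: selection and normalizer stats unchanged
        X = frame(rng.normal(size=(60, 5)))
        y = X["f2"].to_numpy() + 0.05 * rng.normal(size=60)
        train_idx = np.arange(40)
        t1 = train_model(X.iloc[train_idx], y[train_idx], "mlr")
        X_mut = X.copy()
        X_mut.iloc[40:] = 999.0
        t2 = train_model(X_mut.iloc[train_idx], y[train_idx], "mlr")
        assert t1.selected == t2.selected
        assert np.allclose(t1.normalizer.mean, t2.normalizer.mean)
        assert np.allclose(t1.normalizer.sd, t2.normalizer.sd)
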