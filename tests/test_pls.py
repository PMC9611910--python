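"""PLS1 engine: NIPALS correctness, LOO cross-validation, metrics."""

import numpy as np
import pandas as pd
import pytest

from ionoqspr import RankError, compute_metrics, fit_pls, loo_cv, predict
from ionoqspr.pls import predict_via_latent


def random_system(rng, n=15, p=4):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)])
    y = rng.normal(size=n)
    return X, y


def ols_predictions(X, y):
    """Oracle: ordinary least squares via normal equations on centered data."""
    V = X.to_numpy(float)
    Vc = V - V.mean(0)
    yc = y - y.mean()
    beta = np.linalg.solve(Vc.T @ Vc, Vc.T @ yc)
    return Vc @ beta + y.mean()


class TestFitPredict:
    def test_exact_linear_single_column(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        y = [2.0, 4.0, 6.0]
        model = fit_pls(X, y, n_lv=1)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-12)
        assert compute_metrics(y, predict(model, X), "calibration").rmse < 1e-12

    def test_full_rank_pls_equals_ols(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X, y = random_system(rng)
            model = fit_pls(X, y, n_lv=X.shape[1])
            np.testing.assert_allclose(predict(model, X), ols_predictions(X, y),
                                       atol=1e-8)

    def test_matches_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X, y = random_system(rng, n=20, p=6)
        model = fit_pls(X, y, n_lv=3)
        ref = PLSRegression(n_components=3, scale=True).fit(X.to_numpy(), y)
        np.testing.assert_allclose(predict(model, X),
                                   ref.predict(X.to_numpy()).ravel(), atol=1e-8)

    def test_constant_column_dropped(self, rng):
        X, y = random_system(rng)
        X2 = X.copy()
        X2["const"] = 5
        a = fit_pls(X, y, n_lv=2)
        b = fit_pls(X2, y, n_lv=2)
        assert b.kept_columns == a.kept_columns
        np.testing.assert_allclose(predict(b, X2), predict(a, X), atol=1e-12)

    def test_latent_route_equals_coefficient_route(self, rng):
        X, y = random_system(rng, n=20, p=6)
        model = fit_pls(X, y, n_lv=4)
        np.testing.assert_allclose(predict_via_latent(model, X), predict(model, X),
                                   atol=1e-8)

    def test_column_permutation_invariance(self, rng):
        X, y = random_system(rng)
        model = fit_pls(X, y, n_lv=2)
        shuffled = X[list(reversed(X.columns))]
        model2 = fit_pls(shuffled, y, n_lv=2)
        np.testing.assert_allclose(predict(model2, X), predict(model, shuffled),
                                   atol=1e-10)

    def test_column_scaling_absorbed_by_autoscaling(self, rng):
        X, y = random_system(rng)
        scaled = X.copy()
        scaled["f0"] = scaled["f0"] * 7.0
        a = fit_pls(X, y, n_lv=2)
        b = fit_pls(scaled, y, n_lv=2)
        np.testing.assert_allclose(predict(b, scaled), predict(a, X), atol=1e-10)

    def test_calibration_rmse_non_increasing_in_lv(self, rng):
        X, y = random_system(rng, n=20, p=6)
        rmses = []
        for a in range(1, 7):
            model = fit_pls(X, y, n_lv=a)
            rmses.append(compute_metrics(y, predict(model, X), "calibration").rmse)
        assert all(r2 <= r1 + 1e-10 for r1, r2 in zip(rmses, rmses[1:]))

    def test_errors(self, rng):
        X, y = random_system(rng, n=10, p=3)
        with pytest.raises(RankError):
            fit_pls(X, y, n_lv=5)  # rank is at most 3
        with pytest.raises(ValueError, match="3 training rows"):
            fit_pls(X.iloc[:2], y[:2], n_lv=1)
        with pytest.raises(ValueError, match="missing"):
            fit_pls(X, np.r_[y[:-1], np.nan], n_lv=1)

    def test_predict_names_missing_columns(self, rng):
        X, y = random_system(rng)
        model = fit_pls(X, y, n_lv=2)
        with pytest.raises(ValueError, match="f3"):
            predict(model, X[["f0", "f1", "f2"]])

    def test_model_dict_round_trip_is_exact(self, rng):
        X, y = random_system(rng)
        model = fit_pls(X, y, n_lv=2)
        from ionoqspr.pls import PLSModel

        back = PLSModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(back.b_raw, model.b_raw)
        np.testing.assert_array_equal(back.x_scale, model.x_scale)
        assert back.intercept == model.intercept
        assert back.kept_columns == model.kept_columns


class TestLOOCV:
    def test_noiseless_linear_selects_one_lv(self):
        X = pd.DataFrame({"f": np.arange(1.0, 9.0)})
        y = 3.0 * X["f"].to_numpy() + 1.0
        result = loo_cv(X, y, max_lv=3)
        assert result.selected_lv == 1
        assert result.rmsecv[0] < 1e-8

    def test_exactly_n_folds(self, rng):
        """Each sample's LOO prediction equals a from-scratch fit on the
        other n−1 samples — verified fold by fold."""
        X, y = random_system(rng, n=5, p=2)
        result = loo_cv(X, y, max_lv=2)
        assert result.predictions.shape == (2, 5)
        for i in range(5):
            rest = [j for j in range(5) if j != i]
            model = fit_pls(X.iloc[rest], y[rest], n_lv=2)
            expected = predict(model, X.iloc[[i]])[0]
            assert result.predictions[1, i] == pytest.approx(expected, abs=1e-10)

    def test_rmsecv_non_negative_and_bounds_enforced(self, rng):
        X, y = random_system(rng, n=8, p=3)
        result = loo_cv(X, y, max_lv=3)
        assert (result.rmsecv >= 0).all()
        with pytest.raises(ValueError):
            loo_cv(X, y, max_lv=8)

    def test_noise_floor_on_fragment_additive_data(self):
        """Min RMSECV lands within [0.5σ, 2σ] when the data follow a planted
        fragment-additive law with noise sd σ."""
        from ionoqspr import SyntheticSpec, build_descriptor_matrix, generate_molecules, plant_property

        sigma = 2.0
        floors = []
        for seed in range(5):
            spec = SyntheticSpec(n_molecules=80, seed=seed, noise_sd=sigma)
            graphs = [g for g, _ in generate_molecules(spec)]
            y, _ = plant_property(graphs, spec)
            X = build_descriptor_matrix(graphs)
            floors.append(float(loo_cv(X, y, max_lv=15).rmsecv.min()))
        assert all(0.5 * sigma <= f <= 2.0 * sigma for f in floors)


class TestMetrics:
    def test_perfect_fit(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "calibration")
        assert (m.rmse, m.r2, m.slope) == (0.0, 1.0, 1.0)

    def test_closed_form_rmse(self):
        # residuals 3 and 4 -> rmse = sqrt(25/2)
        m = compute_metrics([0.0, 1.0], [3.0, 5.0], "calibration")
        assert m.rmse == pytest.approx(np.sqrt(25 / 2))

    def test_constant_shift(self):
        y = np.array([1.0, 2.0, 4.0])
        m = compute_metrics(y, y + 1.5, "loo_validation")
        assert m.rmse == pytest.approx(1.5)
        assert m.r2 == pytest.approx(1.0)
        assert m.slope == pytest.approx(1.0)

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compute_metrics([2.0, 2.0], [1.0, 3.0], "calibration")

    def test_constant_predictions_have_zero_r2(self):
        m = compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], "loo_validation")
        assert m.r2 == 0.0
        assert m.slope == 0.0
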