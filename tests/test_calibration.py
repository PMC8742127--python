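import numpy as np
import pytest

from spdri import (
    DEFAULT_INTERCEPT_SURFACE,
    DEFAULT_SLOPE_SURFACE,
    AnalyticCalib,
    InvalidFitError,
    fit_analytic_surface,
    fit_knorm_regression,
    probe_model_surface,
    rank_predictors,
    tune_and_train,
)
from _oracles import ols_normal_equations


class TestKnormRegression:
    def test_exact_line_recovered(self):
        d = [4, 6, 8, 10, 12, 14]
        fit = fit_knorm_regression((x, 2.0 + 0.5 * x) for x in d)
        assert fit.beta0 == pytest.approx(2.0)
        assert fit.beta1 == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_used == 6 and fit.n_missing == 0

    def test_missing_values_skipped_and_counted(self):
        pairs = [(4, 3.0), (6, None), (8, 5.0), (10, 6.0),
                 (12, float("nan")), (14, 9.0)]
        fit = fit_knorm_regression(pairs)
        assert fit.n_used == 4 and fit.n_missing == 2

    def test_matches_normal_equations_oracle(self, rng):
        d = np.arange(4.0, 15.0, 2.0)
        k = 1.3 + 0.42 * d + rng.normal(0, 0.1, d.size)
        fit = fit_knorm_regression(zip(d, k))
        b0, b1 = ols_normal_equations(d, k)
        assert fit.beta0 == pytest.approx(b0, abs=1e-10)
        assert fit.beta1 == pytest.approx(b1, abs=1e-10)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(InvalidFitError):
            fit_knorm_regression([(4, 1.0), (6, None)])


def planted_dataset(rng, n=120, signal_cols=(3, 17)):
    X = rng.uniform(0.5, 6.0, size=(n, 24))
    i, j = signal_cols
    y = DEFAULT_SLOPE_SURFACE(X[:, i], X[:, j])
    return X, np.asarray(y)


class TestImportance:
    def test_planted_signal_ranked_first(self, rng):
        X, y = planted_dataset(rng)
        for rep in range(3):
            res = rank_predictors(X, y, rng=rep, n_trees=40)
            assert set(res.top(2)) == {"x3", "x17"}

    def test_constant_response_warns_and_zeroes(self, rng):
        X = rng.normal(size=(40, 24))
        with pytest.warns(UserWarning, match="constant"):
            res = rank_predictors(X, np.ones(40), rng=0)
        assert np.all(res.scores == 0)

    def test_ranking_invariant_to_affine_predictor_rescaling(self, rng):
        X, y = planted_dataset(rng, n=80)
        a = rank_predictors(X, y, rng=5, n_trees=40)
        X2 = X.copy()
        X2[:, 3] = 1000.0 * X2[:, 3] - 7.0  # monotone affine map
        b = rank_predictors(X2, y, rng=5, n_trees=40)
        assert a.ranking == b.ranking

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="30"):
            rank_predictors(rng.normal(size=(10, 4)), rng.normal(size=10))


class TestEnsembleTuning:
    def test_learnable_function_generalises(self, rng):
        X = rng.uniform(0, 1, size=(120, 2))
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1]
        model = tune_and_train(X[:80], y[:80], rng=0, n_cycles=40)
        pred = model.predict(X[80:])
        ss_res = np.sum((pred - y[80:]) ** 2)
        ss_tot = np.sum((y[80:] - y[80:].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.95

    def test_constant_response_shows_no_spurious_skill(self, rng):
        X = rng.normal(size=(60, 2))
        model = tune_and_train(X, np.full(60, 3.3), rng=1, n_cycles=30)
        assert np.allclose(model.predict(X), 3.3, atol=1e-6)

    def test_final_model_uses_requested_cycles(self, rng):
        X = rng.uniform(0, 1, size=(36, 2))
        y = X[:, 0]
        model = tune_and_train(X, y, rng=2, n_cycles=25)
        assert model.n_cycles == 25
        assert model.method in ("bagging", "lsboost")


class TestAnalyticSurface:
    def grid(self, lo=0.5, hi=6.0, n=20):
        g = np.linspace(lo, hi, n)
        X1, X2 = np.meshgrid(g, g, indexing="ij")
        return X1.ravel(), X2.ravel()

    @pytest.mark.parametrize("surface", [
        DEFAULT_SLOPE_SURFACE, DEFAULT_INTERCEPT_SURFACE,
    ], ids=["slope", "intercept"])
    def test_noise_free_samples_recover_all_coefficients(self, surface):
        x1, x2 = self.grid()
        fit = fit_analytic_surface(x1, x2, surface(x1, x2))
        assert np.allclose(fit.coefficients(), surface.coefficients(),
                           rtol=1e-3)
        resid = fit(x1, x2) - surface(x1, x2)
        assert np.abs(resid).max() < 1e-6

    def test_constant_response_collapses_to_constant(self):
        x1, x2 = self.grid()
        fit = fit_analytic_surface(x1, x2, np.full(x1.size, 2.5))
        assert abs(fit.a1) < 1e-6 and abs(fit.a2) < 1e-6
        assert fit.c == pytest.approx(2.5, abs=1e-6)

    def test_asymptote_is_the_constant_term(self):
        assert DEFAULT_SLOPE_SURFACE.asymptote == pytest.approx(0.1389)
        assert DEFAULT_INTERCEPT_SURFACE.asymptote == pytest.approx(-0.4093)

    def test_degenerate_axis_rejected(self):
        x1 = np.full(20, 1.0)
        x2 = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="span"):
            fit_analytic_surface(x1, x2, x2)


class ConstantModel:
    def predict(self, X):
        return np.full(len(X), 1.5)


class TestProbe:
    def test_band_spans_central_sixty_percent(self):
        x = np.linspace(0.0, 10.0, 50)
        px1, px2, z = probe_model_surface(ConstantModel(), x, x, n_points=200)
        assert px1.min() == pytest.approx(2.0)
        assert px1.max() == pytest.approx(8.0)
        assert np.unique(px1).size == 200
        assert np.unique(px2).size == 200

    def test_constant_model_gives_constant_grid(self):
        x = np.linspace(0.0, 1.0, 30)
        _, _, z = probe_model_surface(ConstantModel(), x, x, n_points=20)
        assert np.allclose(z, 1.5)
        assert z.size == 400
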