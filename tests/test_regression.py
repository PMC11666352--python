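"""Ridge LOO identity, exact-GP closed forms, kernels, back-transforms."""

import math

import numpy as np
import pytest

from taqdesign.dataset import TransformParams
from taqdesign.regression import (GPSpec, Matern, RidgeSpec, SpectralDelta,
                                  fit_gp, fit_ridge, init_spectral_delta,
                                  kernel_eval, load_model, predict,
                                  ridge_loo_residuals, save_model, _augment)

RNG = np.random.default_rng(42)


class TestRidge:
    def test_noiseless_linear_interpolation(self):
        X = RNG.standard_normal((12, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 1.5
        model = fit_ridge(X, y, RidgeSpec((1e-10, 1e-6)))
        assert np.allclose(model.predict_mean(X), y, atol=1e-8)

    @pytest.mark.parametrize("alpha", [1e-3, 0.7, 50.0])
    def test_loo_identity_matches_explicit_refits(self, alpha):
        # brute-force oracle: n refits of the identical penalized model
        X = RNG.standard_normal((18, 5))
        y = X @ RNG.standard_normal(5) + RNG.standard_normal(18)
        loo = ridge_loo_residuals(X, y, alpha)
        A = _augment(X)
        D = np.eye(A.shape[1])
        D[-1, -1] = 0.0
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            coef = np.linalg.solve(A[mask].T @ A[mask] + alpha * D,
                                   A[mask].T @ y[mask])
            assert abs(loo[i] - (y[i] - A[i] @ coef)) < 1e-10

    def test_infinite_alpha_predicts_training_mean(self):
        X = RNG.standard_normal((10, 3))
        y = RNG.standard_normal(10) + 5.0
        model = fit_ridge(X, y, RidgeSpec((1e14,)))
        assert np.allclose(model.predict_mean(X), y.mean(), atol=1e-6)
        assert np.allclose(model.coef[:-1], 0.0, atol=1e-9)

    def test_mape_selection_on_original_scale(self):
        # alpha choice must use back-transformed errors, finite under z-scores
        X = RNG.standard_normal((15, 3))
        y_orig = np.exp(X @ np.array([0.5, -0.3, 0.2]) + 2.0)
        params = TransformParams("log", float(np.mean(np.log(y_orig))),
                                 float(np.std(np.log(y_orig))))
        z = np.asarray(params.forward(y_orig))
        model = fit_ridge(X, z, RidgeSpec((1e-6, 1e-2, 1.0, 100.0)), params)
        assert math.isfinite(model.loo_mape)
        assert model.loo_mape < 0.5

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="all-equal"):
            fit_ridge(RNG.standard_normal((5, 2)), np.ones(5))
        with pytest.raises(ValueError):
            fit_ridge(RNG.standard_normal((2, 2)), np.array([1.0, 2.0]))


class TestKernels:
    def test_spectral_delta_unit_diagonal(self):
        sd = init_spectral_delta(RNG.standard_normal((10, 6)), 8, seed=1)
        x = RNG.standard_normal(6)
        assert kernel_eval(sd, x, x) == pytest.approx(1.0)

    def test_matern_scale_and_monotone_decay(self):
        k = Matern(nu=1.5, lengthscale=2.0, variance=3.0)
        x = np.zeros(3)
        assert kernel_eval(k, x, x) == pytest.approx(3.0)
        vals = [kernel_eval(k, x, np.full(3, d)) for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval(Matern(), np.zeros(3), np.zeros(4))

    @pytest.mark.parametrize("make", [
        lambda X: Matern(nu=1.5, lengthscale=1.3),
        lambda X: Matern(nu=2.5, lengthscale=0.7, variance=2.0),
        lambda X: init_spectral_delta(X, 12, seed=3),
    ])
    def test_gram_matrices_are_psd(self, make):
        X = np.random.default_rng(7).standard_normal((20, 5))
        K = make(X)(X, X)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestGP:
    def test_posterior_matches_closed_form_oracle(self):
        # independent direct implementation of the textbook equations
        X = RNG.standard_normal((5, 3))
        y = RNG.standard_normal(5)
        Xs = RNG.standard_normal((3, 3))
        noise = 0.05
        kernel = Matern(nu=2.5, lengthscale=1.2, variance=1.7)
        model = fit_gp(X, y, GPSpec(noise=noise, optimize=False,
                                    lengthscale=1.2))
        model.kernel = kernel  # fix hyperparameters to the oracle's
        from taqdesign.regression import _finalize_gp
        model = _finalize_gp(kernel, X, y - y.mean(), float(y.mean()), noise, [])
        mu, var = model.predict_mean_var(Xs)
        K = kernel(X, X) + noise * np.eye(5)
        Ks = kernel(Xs, X)
        Kss = kernel(Xs, Xs)
        Kinv = np.linalg.inv(K)
        mu_oracle = y.mean() + Ks @ Kinv @ (y - y.mean())
        var_oracle = np.diag(Kss - Ks @ Kinv @ Ks.T)
        assert np.allclose(mu, mu_oracle, atol=1e-6)
        assert np.allclose(var, var_oracle, atol=1e-6)

    def test_zero_noise_interpolates_training_targets(self):
        X = np.linspace(0, 5, 8)[:, None]
        y = np.sin(X[:, 0])
        model = fit_gp(X, y, GPSpec(noise=0.0, optimize=False, lengthscale=1.0))
        mu, _ = model.predict_mean_var(X)
        assert np.allclose(mu, y, atol=1e-6)

    def test_far_point_variance_approaches_prior(self):
        X = RNG.standard_normal((6, 2))
        y = RNG.standard_normal(6)
        model = fit_gp(X, y, GPSpec(noise=1e-4, optimize=False, lengthscale=0.8))
        _, var = model.predict_mean_var(np.array([[100.0, 100.0]]))
        prior = model.kernel.diag(np.array([[100.0, 100.0]]))[0]
        assert var[0] == pytest.approx(prior, rel=1e-6)

    def test_lml_trace_is_monotone_nondecreasing(self):
        X = RNG.standard_normal((20, 4))
        y = np.sin(X[:, 0]) + 0.1 * RNG.standard_normal(20)
        model = fit_gp(X, y, GPSpec(seed=0))
        trace = model.lml_trace
        assert len(trace) >= 2
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))
        assert model.lml >= trace[0] - 1e-8

    def test_deterministic_given_seed(self):
        X = RNG.standard_normal((15, 4))
        y = X[:, 0] ** 2 + 0.1 * RNG.standard_normal(15)
        m1 = fit_gp(X, y, GPSpec(kernel="spectral_delta", num_deltas=4, seed=5))
        m2 = fit_gp(X, y, GPSpec(kernel="spectral_delta", num_deltas=4, seed=5))
        mu1, _ = m1.predict_mean_var(X)
        mu2, _ = m2.predict_mean_var(X)
        assert np.array_equal(mu1, mu2)

    def test_nan_inputs_rejected(self):
        X = RNG.standard_normal((5, 2))
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="NaN"):
            fit_gp(X, y)

    def test_duplicate_training_point_shifts_little(self):
        # adding a consistent duplicate acts like lowering effective noise:
        # predictions move, but only modestly
        X = RNG.standard_normal((10, 3))
        y = X[:, 0] + 0.05 * RNG.standard_normal(10)
        spec = GPSpec(noise=0.1, optimize=False, lengthscale=1.0)
        base = fit_gp(X, y, spec)
        dup = fit_gp(np.vstack([X, X[:1]]), np.append(y, y[0]), spec)
        Xs = RNG.standard_normal((5, 3))
        mu_a, _ = base.predict_mean_var(Xs)
        mu_b, _ = dup.predict_mean_var(Xs)
        assert np.max(np.abs(mu_a - mu_b)) < 0.5 * np.std(y)


class TestPredictiveDistribution:
    def test_identity_target_degenerate(self):
        model = _constant_gp(mu=2.0)
        d = predict(model, np.zeros((1, 1)), TransformParams("identity", 0, 1))[0]
        assert d.mean == pytest.approx(2.0, abs=1e-9)
        assert d.median == pytest.approx(2.0, abs=1e-9)

    def test_log_target_degenerate(self):
        model = _constant_gp(mu=0.0)
        d = predict(model, np.zeros((1, 1)), TransformParams("log", 0, 1))[0]
        assert d.mean == pytest.approx(1.0, abs=1e-6)

    def test_lognormal_mean_matches_monte_carlo(self):
        # mu=1, sigma=0.5 on the log scale -> mean exp(1.125)
        from taqdesign.regression import _summaries
        d = _summaries(1.0, 0.5, TransformParams("log", 0, 1), 0.9)
        assert d.mean == pytest.approx(math.exp(1.125), rel=1e-12)
        draws = np.exp(np.random.default_rng(0).normal(1.0, 0.5, 1_000_000))
        assert d.mean == pytest.approx(draws.mean(), rel=5e-3)
        assert d.median == pytest.approx(math.exp(1.0))

    def test_quantiles_monotone_in_level(self):
        from taqdesign.regression import _summaries
        params = TransformParams("log", 0.3, 0.7)
        widths = []
        for level in (0.5, 0.8, 0.95):
            d = _summaries(0.2, 0.4, params, level)
            assert d.lower <= d.median <= d.upper
            widths.append(d.upper - d.lower)
        assert widths == sorted(widths)

    def test_back_transform_preserves_ordering(self):
        from taqdesign.regression import _summaries
        params = TransformParams("log", 0.0, 1.0)
        d1 = _summaries(0.5, 0.3, params, 0.9)
        d2 = _summaries(1.5, 0.3, params, 0.9)
        assert d1.mean < d2.mean and d1.median < d2.median
        assert d1.lower < d2.lower and d1.upper < d2.upper


def _constant_gp(mu: float):
    from taqdesign.regression import _finalize_gp
    X = np.zeros((3, 1))
    y = np.full(3, mu)
    return _finalize_gp(Matern(lengthscale=1.0), X, y - mu, mu, 0.0, [])


def test_model_serialization_roundtrip(tmp_path):
    X = RNG.standard_normal((8, 3))
    y = X[:, 0] + 0.1 * RNG.standard_normal(8)
    params = TransformParams("log", 1.0, 0.5)
    gp = fit_gp(X, y, GPSpec(seed=1))
    save_model(gp, params, tmp_path / "gp.json")
    loaded, lparams = load_model(tmp_path / "gp.json")
    Xs = RNG.standard_normal((4, 3))
    for a, b in zip(predict(gp, Xs, params), predict(loaded, Xs, lparams)):
        assert a.mean == pytest.approx(b.mean, rel=1e-10)
        assert a.sigma == pytest.approx(b.sigma, rel=1e-10)
    ridge = fit_ridge(X, y)
    save_model(ridge, None, tmp_path / "ridge.json")
    loaded_r, _ = load_model(tmp_path / "ridge.json")
    assert np.allclose(loaded_r.predict_mean(Xs), ridge.predict_mean(Xs))
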