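"""Per-property predictors on sequence embeddings.

Two model families, matching the two phases of a low-N design campaign:

* Ridge regression for the first round, with the penalty strength chosen by
  leave-one-out cross-validation scored as mean absolute percentage error on
  the original measurement scale. LOO residuals come from the closed-form
  linear-smoother identity e_i / (1 - h_ii), so the grid search needs no refits.

* Exact Gaussian-process regression for later rounds, with Matern (nu = 1.5
  or 2.5) or spectral-delta kernels. The posterior is computed by Cholesky
  factorization of K + sigma_n^2 I with jitter escalation, and kernel
  hyperparameters maximize the log marginal likelihood from a seeded start.

Predictions are returned as per-target posterior means and standard
deviations on the modeling (z-scored, possibly log) scale, together with the
back-transformed original-scale mean, median and a central interval. For
log-transformed targets the original-scale summaries are the lognormal ones:
mean = exp(mu + sigma^2 / 2), median = exp(mu).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, cholesky
from scipy.spatial.distance import cdist, pdist
from scipy.stats import norm

from .dataset import TransformParams

MAPE_FLOOR = 1e-6  # |y| floor so MAPE never divides by ~0


# --------------------------------------------------------------------------
# Ridge with LOO-CV / MAPE alpha selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RidgeSpec:
    alpha_grid: tuple[float, ...] = tuple(10.0 ** k for k in range(-4, 5))

    def __post_init__(self) -> None:
        if not self.alpha_grid:
            raise ValueError("alpha grid must be non-empty")
        if any(a <= 0 for a in self.alpha_grid):
            raise ValueError("alphas must be positive")
        object.__setattr__(self, "alpha_grid", tuple(sorted(self.alpha_grid)))


@dataclass
class RidgeModel:
    coef: np.ndarray          # includes the (penalized) intercept feature
    alpha: float
    loo_mape: float
    loo_mape_by_alpha: dict[float, float]

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        A = _augment(np.asarray(X, dtype=float))
        return A @ self.coef


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _ridge_solve(A: np.ndarray, y: np.ndarray, alpha: float):
    """Coefficients, fitted values and leverages of ridge with an
    unpenalized intercept (the last column of A)."""
    p = A.shape[1]
    D = np.eye(p)
    D[-1, -1] = 0.0
    M = A.T @ A + alpha * D
    Minv_At = np.linalg.solve(M, A.T)
    coef = Minv_At @ y
    h = np.einsum("ij,ji->i", A, Minv_At)
    return coef, A @ coef, h


def ridge_loo_residuals(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """LOO residuals via the linear-smoother identity e_i / (1 - h_ii).

    The fit is penalized least squares with a fixed penalty matrix (the
    intercept is unpenalized), for which the identity is exact.
    """
    A = _augment(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    _, fitted, h = _ridge_solve(A, y, alpha)
    return (y - fitted) / (1.0 - h)


def fit_ridge(X: np.ndarray, y: np.ndarray, spec: RidgeSpec = RidgeSpec(),
              transform: TransformParams | None = None) -> RidgeModel:
    """Fit ridge regression with alpha selected by LOO MAPE.

    ``y`` is on the modeling scale; MAPE is evaluated after back-transforming
    LOO predictions (and the truth) with ``transform``, since percentage
    errors on z-scored targets are dominated by near-zero denominators.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training points")
    if np.allclose(y, y[0]):
        raise ValueError("all-equal targets")
    A = _augment(X)
    if np.linalg.matrix_rank(A) == 0:
        raise ValueError("degenerate design matrix")
    inv = (lambda v: v) if transform is None else transform.inverse
    y_orig = np.asarray(inv(y), dtype=float)
    denom = np.maximum(np.abs(y_orig), MAPE_FLOOR)

    mapes: dict[float, float] = {}
    coefs: dict[float, np.ndarray] = {}
    for alpha in spec.alpha_grid:
        coef, fitted, h = _ridge_solve(A, y, alpha)
        loo_pred = y - (y - fitted) / (1.0 - h)
        pred_orig = np.asarray(inv(loo_pred), dtype=float)
        mapes[alpha] = float(np.mean(np.abs(pred_orig - y_orig) / denom))
        coefs[alpha] = coef
    best = min(spec.alpha_grid, key=lambda a: (mapes[a], a))
    return RidgeModel(coef=coefs[best], alpha=best, loo_mape=mapes[best],
                      loo_mape_by_alpha=mapes)


# --------------------------------------------------------------------------
# Kernels
# --------------------------------------------------------------------------

class Kernel:
    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def diag(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class Matern(Kernel):
    """Matern covariance with half-integer smoothness 1.5 or 2.5."""

    nu: float = 2.5
    lengthscale: float = 1.0
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.nu not in (1.5, 2.5):
            raise ValueError("nu must be 1.5 or 2.5")
        if self.lengthscale <= 0:
            raise ValueError("lengthscale must be positive")

    def __call__(self, X1, X2):
        r = cdist(np.atleast_2d(X1), np.atleast_2d(X2)) / self.lengthscale
        if self.nu == 1.5:
            a = math.sqrt(3.0) * r
            k = (1.0 + a) * np.exp(-a)
        else:
            a = math.sqrt(5.0) * r
            k = (1.0 + a + a ** 2 / 3.0) * np.exp(-a)
        return self.variance * k

    def diag(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.variance)


@dataclass
class SpectralDelta(Kernel):
    """Average-of-cosines stationary kernel over Q frequency vectors:
    k(x, x') = (1/Q) sum_q cos(2 pi w_q . (x - x')); k(x, x) = 1."""

    frequencies: np.ndarray  # (Q, d)

    def __post_init__(self) -> None:
        self.frequencies = np.atleast_2d(np.asarray(self.frequencies, dtype=float))
        if self.frequencies.shape[0] < 1:
            raise ValueError("need at least one frequency vector")

    @property
    def num_deltas(self) -> int:
        return self.frequencies.shape[0]

    def __call__(self, X1, X2):
        X1, X2 = np.atleast_2d(X1), np.atleast_2d(X2)
        if X1.shape[1] != X2.shape[1] or X1.shape[1] != self.frequencies.shape[1]:
            raise ValueError("dimension mismatch")
        # phase[q, i, j] = 2 pi w_q . (x_i - x'_j)
        p1 = 2.0 * np.pi * X1 @ self.frequencies.T  # (n1, Q)
        p2 = 2.0 * np.pi * X2 @ self.frequencies.T  # (n2, Q)
        # cos(a - b) = cos a cos b + sin a sin b, summed over q
        return (np.cos(p1) @ np.cos(p2).T + np.sin(p1) @ np.sin(p2).T) / self.num_deltas

    def diag(self, X):
        return np.ones(np.atleast_2d(X).shape[0])


def kernel_eval(kernel: Kernel, x: np.ndarray, x2: np.ndarray) -> float:
    """Evaluate a kernel at a single pair of points."""
    x, x2 = np.asarray(x, dtype=float), np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("dimension mismatch")
    return float(kernel(x[None, :], x2[None, :])[0, 0])


def init_spectral_delta(X: np.ndarray, num_deltas: int = 16, seed: int = 0
                        ) -> SpectralDelta:
    """Seeded frequency initialization scaled by the median pairwise distance."""
    X = np.atleast_2d(X)
    rng = np.random.default_rng(seed)
    dists = pdist(X)
    median = float(np.median(dists[dists > 0])) if np.any(dists > 0) else 1.0
    freqs = rng.standard_normal((num_deltas, X.shape[1])) / (2.0 * np.pi * median)
    return SpectralDelta(freqs)


# --------------------------------------------------------------------------
# Exact GP
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GPSpec:
    """Kernel family and optimizer settings for an exact GP.

    ``kernel`` is "matern" or "spectral_delta"; ``noise`` is the initial
    observation-noise variance (optimized unless ``optimize=False``).
    """

    kernel: str = "matern"
    nu: float = 2.5
    lengthscale: float | None = None  # None: init from median pairwise distance
    num_deltas: int = 16
    noise: float = 1e-2
    optimize: bool = True
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("matern", "spectral_delta"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.num_deltas < 1:
            raise ValueError("need Q >= 1 deltas")


JITTERS = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


def _chol_with_jitter(K: np.ndarray) -> np.ndarray:
    for jitter in JITTERS:
        try:
            return cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("Gram matrix not positive definite after jitter escalation")


def log_marginal_likelihood(kernel: Kernel, X: np.ndarray, y: np.ndarray,
                            noise: float) -> float:
    n = len(y)
    K = kernel(X, X) + noise * np.eye(n)
    L = _chol_with_jitter(K)
    alpha = cho_solve((L, True), y)
    return float(-0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * math.log(2 * math.pi))


@dataclass
class GPModel:
    kernel: Kernel
    noise: float
    X_train: np.ndarray
    y_train: np.ndarray
    y_mean: float
    L: np.ndarray = field(repr=False)
    alpha_vec: np.ndarray = field(repr=False)
    lml: float = 0.0
    lml_trace: list[float] = field(default_factory=list)

    def predict_mean_var(self, Xstar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
        if Xstar.shape[1] != self.X_train.shape[1]:
            raise ValueError("dimension mismatch")
        Ks = self.kernel(Xstar, self.X_train)
        mean = self.y_mean + Ks @ self.alpha_vec
        v = cho_solve((self.L, True), Ks.T)
        var = self.kernel.diag(Xstar) - np.einsum("ij,ji->i", Ks, v)
        return mean, np.maximum(var, 0.0)


def _finalize_gp(kernel: Kernel, X: np.ndarray, yc: np.ndarray, y_mean: float,
                 noise: float, trace: list[float]) -> GPModel:
    K = kernel(X, X) + noise * np.eye(len(yc))
    L = _chol_with_jitter(K)
    alpha_vec = cho_solve((L, True), yc)
    lml = float(-0.5 * yc @ alpha_vec - np.log(np.diag(L)).sum()
                - 0.5 * len(yc) * math.log(2 * math.pi))
    return GPModel(kernel=kernel, noise=noise, X_train=X, y_train=yc + y_mean,
                   y_mean=y_mean, L=L, alpha_vec=alpha_vec, lml=lml,
                   lml_trace=trace)


def fit_gp(X: np.ndarray, y: np.ndarray, spec: GPSpec = GPSpec()) -> GPModel:
    """Fit an exact GP, optimizing hyperparameters by maximum marginal
    likelihood (L-BFGS-B on log-parameters, seeded initialization).

    The recorded ``lml_trace`` holds the log marginal likelihood at each
    accepted optimizer iterate; line search makes it non-decreasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training points")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("NaN or Inf in inputs")
    y_mean = float(np.mean(y))
    yc = y - y_mean

    dists = pdist(X)
    med = float(np.median(dists[dists > 0])) if np.any(dists > 0) else 1.0

    if spec.kernel == "matern":
        ls0 = spec.lengthscale if spec.lengthscale is not None else med
        var0 = max(float(np.var(yc)), 1e-4)

        def build(theta):
            ls, var, noise = np.exp(theta)
            return Matern(nu=spec.nu, lengthscale=ls, variance=var), noise

        theta0 = np.log([ls0, var0, max(spec.noise, 1e-6)])
        bounds = [(math.log(ls0) - 6.0, math.log(ls0) + 6.0),
                  (-10.0, 10.0), (math.log(1e-8), math.log(10.0))]
    else:
        sd0 = init_spectral_delta(X, spec.num_deltas, spec.seed)
        shape = sd0.frequencies.shape

        def build(theta):
            freqs = theta[:-1].reshape(shape)
            return SpectralDelta(freqs), float(np.exp(theta[-1]))

        theta0 = np.concatenate([sd0.frequencies.ravel(),
                                 [np.log(max(spec.noise, 1e-6))]])
        fscale = 10.0 / (2.0 * np.pi * med)
        bounds = [(-fscale, fscale)] * (len(theta0) - 1) \
            + [(math.log(1e-8), math.log(10.0))]

    def objective(theta):
        kernel, noise = build(theta)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                value = -log_marginal_likelihood(kernel, X, yc, noise)
        except (np.linalg.LinAlgError, ValueError):
            return 1e10
        return value if math.isfinite(value) else 1e10

    trace: list[float] = [-objective(theta0)]
    if spec.optimize:
        def callback(theta):
            trace.append(-objective(theta))

        res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": spec.max_iter},
                                callback=callback)
        theta = res.x if -res.fun >= trace[0] else theta0
    else:
        theta = theta0
    kernel, noise = build(theta)
    if not spec.optimize:
        noise = spec.noise  # honor an exact (possibly zero) requested noise
    return _finalize_gp(kernel, X, yc, y_mean, noise, trace)


# --------------------------------------------------------------------------
# Predictive distributions on the original measurement scale
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictiveDistribution:
    """Gaussian posterior on the modeling scale plus original-scale summaries."""

    mu: float
    sigma: float
    mean: float
    median: float
    lower: float
    upper: float
    level: float = 0.9

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _summaries(mu: float, sigma: float, params: TransformParams | None,
               level: float) -> PredictiveDistribution:
    if params is None:
        params = TransformParams("identity", 0.0, 1.0)
    # un-z-scale onto the (possibly log) measurement scale
    m = mu * params.sd + params.mean
    s = sigma * params.sd
    z = norm.ppf(0.5 + level / 2.0)
    if params.transform == "log":
        mean = math.exp(m + 0.5 * s * s)
        median = math.exp(m)
        lower, upper = math.exp(m - z * s), math.exp(m + z * s)
    else:
        mean = median = m
        lower, upper = m - z * s, m + z * s
    return PredictiveDistribution(mu=mu, sigma=sigma, mean=mean, median=median,
                                  lower=lower, upper=upper, level=level)


def predict(model: "GPModel | RidgeModel", Xstar: np.ndarray,
            params: TransformParams | None = None, level: float = 0.9
            ) -> list[PredictiveDistribution]:
    """Per-row predictive distributions, back-transformed to original scale.

    Ridge models carry no predictive variance; their sigma is reported as 0.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if isinstance(model, RidgeModel):
        mus = model.predict_mean(Xstar)
        sds = np.zeros_like(mus)
    elif isinstance(model, GPModel):
        mus, vars_ = model.predict_mean_var(Xstar)
        sds = np.sqrt(vars_ + model.noise)
    else:
        raise TypeError(f"unfitted or unknown model {type(model).__name__}")
    return [_summaries(float(m), float(s), params, level) for m, s in zip(mus, sds)]


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

FORMAT_VERSION = 1


def save_model(model: "GPModel | RidgeModel", params: TransformParams | None,
               path: str | Path) -> None:
    """Versioned JSON on-disk format: kernel spec + hyperparameters +
    training arrays + target transform."""
    if isinstance(model, RidgeModel):
        payload = {"version": FORMAT_VERSION, "family": "ridge",
                   "coef": model.coef.tolist(), "alpha": model.alpha,
                   "loo_mape": model.loo_mape}
    else:
        if isinstance(model.kernel, Matern):
            kspec = {"kind": "matern", "nu": model.kernel.nu,
                     "lengthscale": model.kernel.lengthscale,
                     "variance": model.kernel.variance}
        else:
            kspec = {"kind": "spectral_delta",
                     "frequencies": model.kernel.frequencies.tolist()}
        payload = {"version": FORMAT_VERSION, "family": "gp", "kernel": kspec,
                   "noise": model.noise, "y_mean": model.y_mean,
                   "X_train": model.X_train.tolist(),
                   "y_train": model.y_train.tolist()}
    if params is not None:
        payload["transform"] = {"transform": params.transform,
                                "mean": params.mean, "sd": params.sd}
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path
               ) -> tuple["GPModel | RidgeModel", TransformParams | None]:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('version')}")
    params = None
    if "transform" in payload:
        t = payload["transform"]
        params = TransformParams(t["transform"], t["mean"], t["sd"])
    if payload["family"] == "ridge":
        model: GPModel | RidgeModel = RidgeModel(
            coef=np.asarray(payload["coef"]), alpha=payload["alpha"],
            loo_mape=payload["loo_mape"], loo_mape_by_alpha={})
        return model, params
    k = payload["kernel"]
    kernel: Kernel = (Matern(nu=k["nu"], lengthscale=k["lengthscale"],
                             variance=k["variance"])
                      if k["kind"] == "matern"
                      else SpectralDelta(np.asarray(k["frequencies"])))
    X = np.asarray(payload["X_train"])
    y = np.asarray(payload["y_train"])
    return _finalize_gp(kernel, X, y - payload["y_mean"], payload["y_mean"],
                        payload["noise"], []), params
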