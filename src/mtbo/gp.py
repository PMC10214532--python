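"""Exact Gaussian-process regression with a Matérn 5/2 ARD kernel.

The surrogate used for single-task Bayesian optimization: zero prior mean on
standardized outputs, Matérn 5/2 covariance over a length-scale-weighted
Euclidean distance, trainable Gaussian observation noise, and hyperparameters
chosen by multi-restart maximization of the log marginal likelihood.

All model fitting happens on encoded inputs (continuous coordinates min-max
scaled to [0, 1], categoricals one-hot) and standardized outputs; every
user-facing prediction is returned in original percent-yield units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .domain import ExperimentTable

__all__ = [
    "KernelHyperparams",
    "GPState",
    "weighted_distance",
    "matern52",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit_gp",
    "fit_gp_arrays",
    "posterior",
    "sample_posterior",
    "psd_factor",
]

SQRT5 = np.sqrt(5.0)

# Hyperparameter search box, on log-scale during optimization.  Length
# scales live on [0,1]-encoded inputs, so [1e-3, 1e3] spans everything from
# near-white-noise to effectively flat.
LENGTHSCALE_BOUNDS = (1e-3, 1e3)
SIGNAL_VAR_BOUNDS = (1e-8, 1e4)
NOISE_VAR_BOUNDS = (1e-6, 1e2)  # floor keeps the covariance invertible
N_RESTARTS_DEFAULT = 8


@dataclass(frozen=True)
class KernelHyperparams:
    """Matérn 5/2 ARD hyperparameters on standardized-output units.

    sigma2        signal variance (kernel output scale)
    lengthscales  one positive scale per encoded input dimension
    noise_var     Gaussian observation-noise variance
    """

    sigma2: float
    lengthscales: np.ndarray
    noise_var: float

    def __post_init__(self) -> None:
        ls = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        object.__setattr__(self, "lengthscales", ls)
        if self.sigma2 <= 0 or self.noise_var <= 0 or np.any(ls <= 0):
            raise ValueError("kernel hyperparameters must be strictly positive")


@dataclass
class GPState:
    """A trained GP: data, hyperparameters, and the cached Cholesky factor."""

    X: np.ndarray  # (N, D) encoded inputs
    y_std: np.ndarray  # (N,) standardized outputs
    y_mean: float
    y_sd: float
    hyperparams: KernelHyperparams
    chol: np.ndarray  # lower factor of K + noise I + jitter I
    alpha: np.ndarray  # (K + noise I + jitter I)^{-1} y_std
    jitter: float
    log_marginal: float

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def best_observed(self) -> float:
        """Incumbent y*: the best observed yield, in percent units."""
        return float(np.max(self.y_std) * self.y_sd + self.y_mean)


# ---------------------------------------------------------------------------
# kernel


def weighted_distance(x: np.ndarray, x2: np.ndarray, lengthscales: np.ndarray) -> float:
    """Euclidean distance between two points, weighted per-dimension by L."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    L = np.asarray(lengthscales, dtype=float)
    if x.shape != x2.shape or x.shape != L.shape:
        raise ValueError("x, x2 and lengthscales must have equal lengths")
    return float(np.sqrt(np.sum(((x - x2) / L) ** 2)))


def _matern52_of_d(d: np.ndarray) -> np.ndarray:
    return (1.0 + SQRT5 * d + (5.0 / 3.0) * d * d) * np.exp(-SQRT5 * d)


def matern52(x: np.ndarray, x2: np.ndarray, hyperparams: KernelHyperparams) -> float:
    """Matérn 5/2 covariance between two encoded points."""
    d = weighted_distance(x, x2, hyperparams.lengthscales)
    return float(hyperparams.sigma2 * _matern52_of_d(np.asarray(d)))


def _pairwise_d(X1: np.ndarray, X2: np.ndarray, lengthscales: np.ndarray) -> np.ndarray:
    Z1 = X1 / lengthscales
    Z2 = X2 / lengthscales
    d2 = np.sum(Z1 * Z1, axis=1)[:, None] + np.sum(Z2 * Z2, axis=1)[None, :] - 2.0 * Z1 @ Z2.T
    return np.sqrt(np.maximum(d2, 0.0))


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, hyperparams: KernelHyperparams) -> np.ndarray:
    """Dense Matérn 5/2 cross-covariance matrix."""
    return hyperparams.sigma2 * _matern52_of_d(_pairwise_d(X1, X2, hyperparams.lengthscales))


# ---------------------------------------------------------------------------
# factorization with escalating jitter


def chol_with_jitter(K: np.ndarray, base_jitter: float) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K + jitter*I, escalating jitter x10 on failure.

    Starts from ``base_jitter`` and gives up at 1e-2 * mean diagonal; a
    failure there is reported, never silently absorbed.
    """
    scale = max(float(np.mean(np.diag(K))), 1e-12)
    jitter = base_jitter
    while jitter <= 1e-2 * scale * (1.0 + 1e-12):
        try:
            L = cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        "covariance not positive definite even after jitter escalation"
    )


# ---------------------------------------------------------------------------
# marginal likelihood


def _lml_from_chol(L: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    alpha = cho_solve((L, True), y)
    n = y.shape[0]
    value = -0.5 * float(y @ alpha) - float(np.sum(np.log(np.diag(L)))) - 0.5 * n * np.log(2.0 * np.pi)
    return value, alpha


def log_marginal_likelihood(X: np.ndarray, y_std: np.ndarray, hyperparams: KernelHyperparams) -> float:
    """Gaussian log marginal likelihood of standardized outputs.

    -1/2 y^T S^{-1} y - 1/2 log|S| - N/2 log 2pi with S = K + noise I
    (plus the numerical jitter used to factorize).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y_std, dtype=float).ravel()
    K = kernel_matrix(X, X, hyperparams) + hyperparams.noise_var * np.eye(X.shape[0])
    L, _ = chol_with_jitter(K, 1e-6 * hyperparams.sigma2)
    return _lml_from_chol(L, y)[0]


def _sq_diffs(X: np.ndarray) -> np.ndarray:
    """(D, N, N) tensor of per-dimension squared coordinate differences."""
    return (X.T[:, :, None] - X.T[:, None, :]) ** 2


def _make_lml_objective(X: np.ndarray, y: np.ndarray):
    """Build the (value, grad) LML objective over [log sigma2, log L, log noise].

    Per-dimension squared differences are precomputed once; the gradient
    uses the standard identity d(LML)/dtheta = 1/2 tr((aa^T - S^{-1}) dS/dtheta)
    with a = S^{-1} y.
    """
    n, D = X.shape
    diff2 = _sq_diffs(X)  # (D, N, N)
    diff2_flat = diff2.reshape(D, -1)
    eye = np.eye(n)

    def objective(log_params: np.ndarray) -> tuple[float, np.ndarray]:
        sigma2 = np.exp(log_params[0])
        L_ = np.exp(log_params[1 : 1 + D])
        noise = np.exp(log_params[1 + D])

        d2 = np.tensordot(1.0 / L_**2, diff2, axes=1)
        d = np.sqrt(np.maximum(d2, 0.0))
        E = np.exp(-SQRT5 * d)
        M = (1.0 + SQRT5 * d + (5.0 / 3.0) * d * d) * E
        K = sigma2 * M + noise * eye
        Lc, _ = chol_with_jitter(K, 1e-6 * sigma2)
        value, alpha = _lml_from_chol(Lc, y)

        Kinv = cho_solve((Lc, True), eye)
        W = np.outer(alpha, alpha) - Kinv  # d(LML)/dK = W/2

        grad = np.empty(1 + D + 1)
        grad[0] = 0.5 * np.sum(W * (sigma2 * M))
        # dK/dlogL_j = sigma2 * (5/3)(1 + sqrt5 d) e^{-sqrt5 d} * (dx_j/L_j)^2
        WG = (W * (sigma2 * (5.0 / 3.0) * (1.0 + SQRT5 * d) * E)).ravel()
        grad[1 : 1 + D] = 0.5 * (diff2_flat @ WG) / L_**2
        grad[1 + D] = 0.5 * noise * np.trace(W)
        return value, grad

    return objective


def _multi_restart_maximize(
    objective: Callable[[np.ndarray], tuple[float, np.ndarray]],
    inits: Sequence[np.ndarray],
    bounds: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, float]:
    """Maximize a (value, grad) objective from several starts; keep the best."""

    def neg(p: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            v, g = objective(p)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(p)
        if not np.isfinite(v):
            return 1e12, np.zeros_like(p)
        return -v, -g

    best_p, best_v = None, -np.inf
    for p0 in inits:
        res = minimize(neg, p0, jac=True, method="L-BFGS-B", bounds=bounds, options={"maxiter": 120})
        if np.isfinite(res.fun) and -res.fun > best_v:
            best_v = -float(res.fun)
            best_p = np.asarray(res.x)
    if best_p is None:
        raise np.linalg.LinAlgError("hyperparameter optimization failed from every restart")
    return best_p, best_v


def _standardize(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(y))
    sd = float(np.std(y))
    if sd < 1e-12:
        sd = 1.0  # all-identical outputs: fit proceeds on zeros
    return (y - mean) / sd, mean, sd


def fit_gp_arrays(
    X: np.ndarray,
    y: np.ndarray,
    n_restarts: int = N_RESTARTS_DEFAULT,
    seed: int = 0,
) -> GPState:
    """Fit a GP to encoded inputs and raw percent yields."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on N")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to fit a GP")
    y_std, y_mean, y_sd = _standardize(y)
    D = X.shape[1]

    rng = np.random.default_rng(seed)
    log_bounds = (
        [tuple(np.log(SIGNAL_VAR_BOUNDS))]
        + [tuple(np.log(LENGTHSCALE_BOUNDS))] * D
        + [tuple(np.log(NOISE_VAR_BOUNDS))]
    )
    inits = [np.concatenate([[0.0], np.full(D, np.log(0.5)), [np.log(1e-2)]])]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(
            np.concatenate(
                [
                    rng.uniform(np.log(0.1), np.log(5.0), 1),
                    rng.uniform(np.log(0.05), np.log(3.0), D),
                    rng.uniform(np.log(1e-4), np.log(0.5), 1),
                ]
            )
        )

    p, lml = _multi_restart_maximize(_make_lml_objective(X, y_std), inits, log_bounds)
    hp = KernelHyperparams(float(np.exp(p[0])), np.exp(p[1 : 1 + D]), float(np.exp(p[1 + D])))

    K = kernel_matrix(X, X, hp) + hp.noise_var * np.eye(X.shape[0])
    L, jitter = chol_with_jitter(K, 1e-6 * hp.sigma2)
    value, alpha = _lml_from_chol(L, y_std)
    return GPState(X, y_std, y_mean, y_sd, hp, L, alpha, jitter, value)


def fit_gp(table: ExperimentTable, n_restarts: int = N_RESTARTS_DEFAULT, seed: int = 0) -> GPState:
    """Fit a single-task GP to an experiment table (task labels ignored)."""
    if len(table) < 2:
        raise ValueError("need at least 2 observations to fit a GP")
    return fit_gp_arrays(table.encoded(), table.yields(), n_restarts=n_restarts, seed=seed)


# ---------------------------------------------------------------------------
# posterior


def posterior(state: GPState, Xq: np.ndarray, full_cov: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Exact GP posterior at query points, de-standardized to percent units.

    Returns ``(means, covariance)`` with ``full_cov=True`` (covariance
    symmetrized as (C + C^T)/2), or ``(means, variances)`` otherwise.
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if Xq.shape[1] != state.X.shape[1]:
        raise ValueError(f"query dimension {Xq.shape[1]} != training dimension {state.X.shape[1]}")
    Ks = kernel_matrix(Xq, state.X, state.hyperparams)
    mean_std = Ks @ state.alpha
    V = solve_triangular(state.chol, Ks.T, lower=True)
    if full_cov:
        Kss = kernel_matrix(Xq, Xq, state.hyperparams)
        C = Kss - V.T @ V
        C = 0.5 * (C + C.T)
        return mean_std * state.y_sd + state.y_mean, C * state.y_sd**2
    var = state.hyperparams.sigma2 - np.sum(V * V, axis=0)
    return mean_std * state.y_sd + state.y_mean, np.maximum(var, 0.0) * state.y_sd**2


def psd_factor(C: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Factor F with F F^T ~= C after clipping negative eigenvalues at eps."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    return V * np.sqrt(np.maximum(w, eps))


def sample_posterior(
    state: GPState, Xq: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw joint posterior function samples (n_samples, n_query), percent units."""
    mean, cov = posterior(state, Xq, full_cov=True)
    F = psd_factor(cov)
    Z = rng.standard_normal((n_samples, F.shape[1]))
    return mean[None, :] + Z @ F.T
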