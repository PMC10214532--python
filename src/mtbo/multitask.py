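"""Multitask Gaussian processes via the intrinsic model of coregionalization.

The joint covariance between observations (x, t) and (x', t') factorizes as
``B[t, t'] * k(x, x')`` where k is a unit-variance Matérn 5/2 ARD kernel
shared by all tasks and B is a T x T trainable task covariance.  B is
parameterized as ``A A^T + diag(exp(c))`` (low rank plus positive diagonal),
which keeps it positive semidefinite for every reachable parameter setting;
its off-diagonal entries, normalized by the diagonal, are the learned
inter-task correlations.  The input kernel's signal variance is fixed at 1
so all output scale lives in B, removing the sigma^2 * B ambiguity.

Training maximizes the joint log marginal likelihood over all tasks'
observations, exactly as in the single-task case.  Outputs are standardized
per task (auxiliary campaigns may sit in different yield regimes); tasks
with fewer than two observations fall back to the pooled constants, since a
single point has no spread to standardize by.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .domain import ExperimentTable
from .gp import (
    SQRT5,
    LENGTHSCALE_BOUNDS,
    NOISE_VAR_BOUNDS,
    N_RESTARTS_DEFAULT,
    KernelHyperparams,
    _lml_from_chol,
    _matern52_of_d,
    _multi_restart_maximize,
    _pairwise_d,
    chol_with_jitter,
    psd_factor,
)

__all__ = [
    "TaskKernel",
    "MultiTaskGPState",
    "icm_kernel",
    "fit_mtgp",
    "fit_mtgp_arrays",
    "build_mt_state",
    "mt_posterior",
    "sample_mt_posterior",
]


@dataclass(frozen=True)
class TaskKernel:
    """Task covariance B = A A^T + diag(diag), PSD by construction."""

    factor: np.ndarray  # (T, rank)
    diag: np.ndarray  # (T,) strictly positive

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.factor, dtype=float))
        d = np.atleast_1d(np.asarray(self.diag, dtype=float))
        object.__setattr__(self, "factor", A)
        object.__setattr__(self, "diag", d)
        if A.shape[0] != d.shape[0]:
            raise ValueError("factor rows and diag length disagree on T")
        if np.any(d <= 0):
            raise ValueError("task-kernel diagonal must be strictly positive")

    @property
    def n_tasks(self) -> int:
        return self.factor.shape[0]

    @property
    def B(self) -> np.ndarray:
        return self.factor @ self.factor.T + np.diag(self.diag)

    def correlation(self, t: int, t2: int) -> float:
        B = self.B
        return float(B[t, t2] / np.sqrt(B[t, t] * B[t2, t2]))


@dataclass
class MultiTaskGPState:
    """A trained ICM multitask GP over encoded inputs and task indices."""

    X: np.ndarray  # (N, D)
    t: np.ndarray  # (N,) task indices into task_labels
    y_std: np.ndarray  # (N,) per-task standardized outputs
    task_labels: list[str]
    y_means: np.ndarray  # (T,) per-task standardization constants (percent)
    y_sds: np.ndarray  # (T,)
    input_hp: KernelHyperparams  # sigma2 fixed to 1
    task_kernel: TaskKernel
    chol: np.ndarray
    alpha: np.ndarray
    jitter: float
    log_marginal: float

    @property
    def n_tasks(self) -> int:
        return len(self.task_labels)

    def task_index(self, task: str) -> int:
        try:
            return self.task_labels.index(task)
        except ValueError as err:
            raise ValueError(f"unknown task {task!r}; have {self.task_labels}") from err

    def best_observed(self, task: str) -> float:
        ti = self.task_index(task)
        mask = self.t == ti
        if not np.any(mask):
            raise ValueError(f"task {task!r} has no observations")
        return float(np.max(self.y_std[mask]) * self.y_sds[ti] + self.y_means[ti])

    def task_rows(self, task: str) -> np.ndarray:
        return self.X[self.t == self.task_index(task)]


def icm_kernel(
    x: np.ndarray,
    t: int,
    x2: np.ndarray,
    t2: int,
    input_hp: KernelHyperparams,
    task_kernel: TaskKernel,
) -> float:
    """ICM covariance between (x, t) and (x2, t2): B[t, t2] * matern52(x, x2)."""
    T = task_kernel.n_tasks
    if not (0 <= t < T and 0 <= t2 < T):
        raise ValueError(f"task index out of range [0, {T})")
    d = _pairwise_d(np.atleast_2d(x), np.atleast_2d(x2), input_hp.lengthscales)[0, 0]
    return float(task_kernel.B[t, t2] * _matern52_of_d(np.asarray(d)))


# ---------------------------------------------------------------------------
# joint covariance and likelihood


def _joint_kernel(
    X: np.ndarray, t: np.ndarray, input_hp: KernelHyperparams, task_kernel: TaskKernel
) -> np.ndarray:
    M = _matern52_of_d(_pairwise_d(X, X, input_hp.lengthscales))
    B = task_kernel.B
    return B[np.ix_(t, t)] * M


def _make_mt_lml_objective(X: np.ndarray, t: np.ndarray, y: np.ndarray, rank: int):
    """Build the joint-LML objective over [log L (D), A (T*rank), c (T), log noise]."""
    N, D = X.shape
    T = int(t.max()) + 1
    diff2 = (X.T[:, :, None] - X.T[:, None, :]) ** 2  # (D, N, N)
    diff2_flat = diff2.reshape(D, -1)
    eye = np.eye(N)
    P = np.zeros((T, N))
    P[t, np.arange(N)] = 1.0

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        A = params[D : D + T * rank].reshape(T, rank)
        c = params[D + T * rank : D + T * rank + T]
        noise = np.exp(params[-1])
        L_ = np.exp(params[:D])

        d2 = np.tensordot(1.0 / L_**2, diff2, axes=1)
        d = np.sqrt(np.maximum(d2, 0.0))
        E = np.exp(-SQRT5 * d)
        M = (1.0 + SQRT5 * d + (5.0 / 3.0) * d * d) * E
        B = A @ A.T + np.diag(np.exp(c))
        Bmat = B[np.ix_(t, t)]
        K = Bmat * M + noise * eye
        Lc, _ = chol_with_jitter(K, 1e-6 * max(float(np.max(np.diag(B))), 1e-8))
        value, alpha = _lml_from_chol(Lc, y)

        Kinv = cho_solve((Lc, True), eye)
        W = np.outer(alpha, alpha) - Kinv

        grad = np.empty_like(params)
        # input lengthscales
        WG = (W * ((5.0 / 3.0) * (1.0 + SQRT5 * d) * E * Bmat)).ravel()
        grad[:D] = 0.5 * (diff2_flat @ WG) / L_**2
        # task factor A: grad[p, q] = mask_p^T (W.M) a_q with a_q[n] = A[t_n, q]
        WM = W * M
        grad[D : D + T * rank] = (P @ (WM @ A[t, :])).ravel()
        # task diagonal (log-scale): 0.5 exp(c_p) mask_p^T WM mask_p
        grad[D + T * rank : D + T * rank + T] = 0.5 * np.exp(c) * np.einsum(
            "pn,nm,pm->p", P, WM, P
        )
        grad[-1] = 0.5 * noise * np.trace(W)
        return value, grad

    return objective


# ---------------------------------------------------------------------------
# fitting


def _per_task_standardize(
    y: np.ndarray, t: np.ndarray, T: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pooled_mean = float(np.mean(y))
    pooled_sd = float(np.std(y))
    if pooled_sd < 1e-12:
        pooled_sd = 1.0
    means = np.empty(T)
    sds = np.empty(T)
    for ti in range(T):
        yt = y[t == ti]
        if yt.size < 2 or float(np.std(yt)) < 1e-8:
            means[ti] = pooled_mean if yt.size == 0 else float(np.mean(yt))
            sds[ti] = pooled_sd
        else:
            means[ti] = float(np.mean(yt))
            sds[ti] = float(np.std(yt))
    return (y - means[t]) / sds[t], means, sds


def fit_mtgp_arrays(
    X: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    task_labels: list[str],
    rank: int | None = None,
    n_restarts: int = N_RESTARTS_DEFAULT,
    seed: int = 0,
) -> MultiTaskGPState:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=int)
    y = np.asarray(y, dtype=float).ravel()
    T = len(task_labels)
    for ti, label in enumerate(task_labels):
        if not np.any(t == ti):
            raise ValueError(f"task {label!r} has zero observations")
    if rank is None:
        rank = min(T, 2)
    D = X.shape[1]
    y_std, means, sds = _per_task_standardize(y, t, T)

    rng = np.random.default_rng(seed)
    bounds = (
        [tuple(np.log(LENGTHSCALE_BOUNDS))] * D
        + [(-10.0, 10.0)] * (T * rank)  # A unconstrained within a sane box
        + [(np.log(1e-6), np.log(1e2))] * T  # log task diagonal
        + [tuple(np.log(NOISE_VAR_BOUNDS))]
    )
    # First start: moderate lengthscales, near-identity B with mild sharing.
    A0 = np.full((T, rank), 0.0)
    A0[:, 0] = 0.7
    inits = [
        np.concatenate([np.full(D, np.log(0.5)), A0.ravel(), np.full(T, np.log(0.3)), [np.log(1e-2)]])
    ]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(
            np.concatenate(
                [
                    rng.uniform(np.log(0.05), np.log(3.0), D),
                    rng.normal(0.0, 0.7, T * rank),
                    rng.uniform(np.log(0.05), np.log(1.0), T),
                    rng.uniform(np.log(1e-4), np.log(0.5), 1),
                ]
            )
        )

    p, lml = _multi_restart_maximize(_make_mt_lml_objective(X, t, y_std, rank), inits, bounds)
    A = p[D : D + T * rank].reshape(T, rank)
    task_kernel = TaskKernel(A, np.exp(p[D + T * rank : D + T * rank + T]))
    input_hp = KernelHyperparams(1.0, np.exp(p[:D]), float(np.exp(p[-1])))
    return build_mt_state(X, t, y, task_labels, input_hp, task_kernel)


def fit_mtgp(
    table: ExperimentTable,
    rank: int | None = None,
    n_restarts: int = N_RESTARTS_DEFAULT,
    seed: int = 0,
    task_labels: list[str] | None = None,
) -> MultiTaskGPState:
    """Fit the ICM multitask GP jointly on all tasks in the table.

    ``task_labels`` fixes the task index order (and triggers a rejection if
    a listed task has no rows); by default tasks are indexed in order of
    first appearance.
    """
    labels = task_labels if task_labels is not None else table.task_labels
    present = set(table.tasks())
    for label in labels:
        if label not in present:
            raise ValueError(f"task {label!r} has zero observations")
    index = {label: i for i, label in enumerate(labels)}
    t = np.array([index[task] for task in table.tasks()], dtype=int)
    return fit_mtgp_arrays(
        table.encoded(), t, table.yields(), list(labels), rank=rank, n_restarts=n_restarts, seed=seed
    )


def build_mt_state(
    X: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    task_labels: list[str],
    input_hp: KernelHyperparams,
    task_kernel: TaskKernel,
) -> MultiTaskGPState:
    """Assemble a state from given hyperparameters (no fitting)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=int)
    y = np.asarray(y, dtype=float).ravel()
    T = len(task_labels)
    y_std, means, sds = _per_task_standardize(y, t, T)
    K = _joint_kernel(X, t, input_hp, task_kernel) + input_hp.noise_var * np.eye(X.shape[0])
    base = 1e-6 * max(float(np.max(np.diag(task_kernel.B))), 1e-8)
    Lc, jitter = chol_with_jitter(K, base)
    value, alpha = _lml_from_chol(Lc, y_std)
    return MultiTaskGPState(
        X, t, y_std, list(task_labels), means, sds, input_hp, task_kernel, Lc, alpha, jitter, value
    )


# ---------------------------------------------------------------------------
# posterior


def mt_posterior(
    state: MultiTaskGPState, Xq: np.ndarray, task: str, full_cov: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Joint-GP posterior restricted to (Xq, task), in percent units."""
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if Xq.shape[1] != state.X.shape[1]:
        raise ValueError(f"query dimension {Xq.shape[1]} != training dimension {state.X.shape[1]}")
    ti = state.task_index(task)
    B = state.task_kernel.B
    M_cross = _matern52_of_d(_pairwise_d(Xq, state.X, state.input_hp.lengthscales))
    Ks = B[ti, state.t][None, :] * M_cross
    mean_std = Ks @ state.alpha
    V = solve_triangular(state.chol, Ks.T, lower=True)
    sd = state.y_sds[ti]
    mean = mean_std * sd + state.y_means[ti]
    if full_cov:
        Kss = B[ti, ti] * _matern52_of_d(_pairwise_d(Xq, Xq, state.input_hp.lengthscales))
        C = Kss - V.T @ V
        C = 0.5 * (C + C.T)
        return mean, C * sd**2
    var = B[ti, ti] - np.sum(V * V, axis=0)
    return mean, np.maximum(var, 0.0) * sd**2


def sample_mt_posterior(
    state: MultiTaskGPState, Xq: np.ndarray, task: str, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    mean, cov = mt_posterior(state, Xq, task, full_cov=True)
    F = psd_factor(cov)
    Z = rng.standard_normal((n_samples, F.shape[1]))
    return mean[None, :] + Z @ F.T
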