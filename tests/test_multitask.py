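"""ICM multitask GP: kernel structure, joint posterior, transfer behavior.

Brute-force oracles build the joint task-by-input covariance entrywise with
explicit inverses; transfer properties are checked by simulation against
latent functions with known inter-task relationships.
"""

import numpy as np
import pytest

from mtbo.gp import KernelHyperparams, fit_gp_arrays, kernel_matrix, posterior
from mtbo.multitask import (
    TaskKernel,
    build_mt_state,
    fit_mtgp_arrays,
    icm_kernel,
    mt_posterior,
)
from mtbo.gp import matern52
from test_gp import make_state


def brute_mt_posterior(X, t, y_std, input_hp, task_kernel, jitter, Xq, tq):
    """Entrywise joint covariance + explicit inverse posterior."""
    n = len(y_std)
    B = task_kernel.B
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = B[t[i], t[j]] * matern52(X[i], X[j], KernelHyperparams(1.0, input_hp.lengthscales, 1e-9))
    S = K + (input_hp.noise_var + jitter) * np.eye(n)
    Sinv = np.linalg.inv(S)
    m = Xq.shape[0]
    Ks = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            Ks[i, j] = B[tq, t[j]] * matern52(Xq[i], X[j], KernelHyperparams(1.0, input_hp.lengthscales, 1e-9))
    Kss = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            Kss[i, j] = B[tq, tq] * matern52(Xq[i], Xq[j], KernelHyperparams(1.0, input_hp.lengthscales, 1e-9))
    return Ks @ Sinv @ y_std, Kss - Ks @ Sinv @ Ks.T


class TestICMKernel:
    def test_identity_task_matrix_decouples_tasks(self):
        tk = TaskKernel(np.zeros((2, 1)), np.ones(2))
        hp = KernelHyperparams(1.0, np.array([0.5]), 1e-6)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x, x2 = rng.uniform(0, 1, 1), rng.uniform(0, 1, 1)
            assert icm_kernel(x, 0, x2, 1, hp, tk) == 0.0

    def test_same_point_same_task_gives_task_variance(self):
        tk = TaskKernel(np.array([[0.5], [1.0]]), np.array([0.2, 0.3]))
        hp = KernelHyperparams(1.0, np.array([0.5]), 1e-6)
        x = np.array([0.4])
        assert icm_kernel(x, 1, x, 1, hp, tk) == pytest.approx(tk.B[1, 1])

    def test_symmetric_under_argument_swap(self):
        tk = TaskKernel(np.array([[0.5], [1.0]]), np.array([0.2, 0.3]))
        hp = KernelHyperparams(1.0, np.array([0.5, 0.8]), 1e-6)
        rng = np.random.default_rng(1)
        for _ in range(10):
            x, x2 = rng.uniform(0, 1, 2), rng.uniform(0, 1, 2)
            assert icm_kernel(x, 0, x2, 1, hp, tk) == pytest.approx(icm_kernel(x2, 1, x, 0, hp, tk), rel=1e-12)

    def test_out_of_range_task_rejected(self):
        tk = TaskKernel(np.zeros((2, 1)), np.ones(2))
        hp = KernelHyperparams(1.0, np.array([0.5]), 1e-6)
        with pytest.raises(ValueError):
            icm_kernel(np.array([0.1]), 2, np.array([0.2]), 0, hp, tk)

    def test_task_matrix_psd_by_construction(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tk = TaskKernel(rng.normal(0, 2, (4, 2)), np.abs(rng.normal(0, 1, 4)) + 1e-6)
            assert np.min(np.linalg.eigvalsh(tk.B)) >= -1e-10


class TestPosteriorOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_joint_formula(self, seed):
        rng = np.random.default_rng(seed)
        n0, n1 = rng.integers(2, 5), rng.integers(2, 5)
        d = rng.integers(1, 3)
        X = rng.uniform(0, 1, (n0 + n1, d))
        t = np.array([0] * n0 + [1] * n1)
        y = rng.uniform(10, 90, n0 + n1)
        tk = TaskKernel(rng.normal(0, 1, (2, 1)), np.abs(rng.normal(0, 0.5, 2)) + 0.1)
        hp = KernelHyperparams(1.0, rng.uniform(0.2, 1.5, d), float(rng.uniform(0.01, 0.3)))
        st = build_mt_state(X, t, y, ["main", "aux"], hp, tk)
        Xq = rng.uniform(0, 1, (4, d))
        mean, cov = mt_posterior(st, Xq, "main")
        bm, bc = brute_mt_posterior(X, t, st.y_std, hp, tk, st.jitter, Xq, 0)
        assert np.max(np.abs(mean - (bm * st.y_sds[0] + st.y_means[0]))) < 1e-8
        assert np.max(np.abs(cov - 0.5 * (bc + bc.T) * st.y_sds[0] ** 2)) < 1e-8

    def test_diagonal_task_matrix_reduces_to_single_task(self):
        rng = np.random.default_rng(10)
        X0 = rng.uniform(0, 1, (6, 1))
        X1 = rng.uniform(0, 1, (9, 1))
        y0 = rng.uniform(20, 80, 6)
        y1 = rng.uniform(20, 80, 9)
        s2 = 1.7
        hp_in = KernelHyperparams(1.0, np.array([0.4]), 0.05)
        tk = TaskKernel(np.zeros((2, 1)), np.array([s2, 0.9]))
        mt = build_mt_state(
            np.vstack([X0, X1]), np.array([0] * 6 + [1] * 9), np.concatenate([y0, y1]),
            ["main", "aux"], hp_in, tk,
        )
        single = make_state(X0, y0, KernelHyperparams(s2, np.array([0.4]), 0.05))
        Xq = rng.uniform(0, 1, (7, 1))
        m_mt, c_mt = mt_posterior(mt, Xq, "main")
        m_st, c_st = posterior(single, Xq)
        assert np.max(np.abs(m_mt - m_st)) < 1e-6
        assert np.max(np.abs(c_mt - c_st)) < 1e-6

    def test_full_correlation_equals_pooled_single_gp(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (7, 1))
        y = rng.uniform(20, 80, 7)
        s = 1.3
        hp_in = KernelHyperparams(1.0, np.array([0.4]), 0.05)
        tk = TaskKernel(np.full((2, 1), np.sqrt(s)), np.full(2, 1e-10))
        Xmt = np.vstack([X, X])
        ymt = np.concatenate([y, y])
        mt = build_mt_state(Xmt, np.array([0] * 7 + [1] * 7), ymt, ["main", "aux"], hp_in, tk)
        pooled = make_state(Xmt, ymt, KernelHyperparams(s, np.array([0.4]), 0.05))
        Xq = rng.uniform(0, 1, (6, 1))
        m_mt, c_mt = mt_posterior(mt, Xq, "main")
        m_p, c_p = posterior(pooled, Xq)
        assert np.max(np.abs(m_mt - m_p)) < 1e-4
        assert np.max(np.abs(c_mt - c_p)) < 1e-4


class TestFitting:
    def test_zero_observation_task_rejected_by_name(self):
        X = np.random.default_rng(0).uniform(0, 1, (4, 1))
        with pytest.raises(ValueError, match="aux"):
            fit_mtgp_arrays(X, np.zeros(4, dtype=int), np.arange(4.0), ["main", "aux"])

    def test_single_task_fit_agrees_with_plain_gp(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (20, 1))
        y = 50 + 25 * np.sin(5 * X[:, 0]) + rng.normal(0, 0.5, 20)
        mt = fit_mtgp_arrays(X, np.zeros(20, dtype=int), y, ["main"], seed=0)
        st = fit_gp_arrays(X, y, seed=0)
        Xq = np.linspace(0, 1, 30)[:, None]
        m_mt, _ = mt_posterior(mt, Xq, "main", full_cov=False)
        m_st, _ = posterior(st, Xq, full_cov=False)
        assert np.max(np.abs(m_mt - m_st)) < 1e-4 * max(1.0, np.max(np.abs(m_st)))

    def test_shared_function_tasks_recover_high_correlation(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            f = lambda x: np.sin(5 * x) + 0.5 * x
            X0 = rng.uniform(0, 1, (12, 1))
            X1 = rng.uniform(0, 1, (12, 1))
            y0 = 50 + 20 * f(X0[:, 0]) + rng.normal(0, 0.5, 12)
            y1 = 45 + 18 * f(X1[:, 0]) + rng.normal(0, 0.5, 12)
            st = fit_mtgp_arrays(
                np.vstack([X0, X1]), np.array([0] * 12 + [1] * 12),
                np.concatenate([y0, y1]), ["main", "aux"], n_restarts=4, seed=seed,
            )
            if st.task_kernel.correlation(0, 1) > 0.5:
                hits += 1
        assert hits >= 16

    def test_independent_tasks_recover_low_correlation(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            hp = KernelHyperparams(1.0, np.array([0.25]), 1e-6)
            X0 = rng.uniform(0, 1, (16, 1))
            X1 = rng.uniform(0, 1, (16, 1))
            # two independent GP draws: unrelated smooth functions
            K0 = kernel_matrix(X0, X0, hp) + 1e-8 * np.eye(16)
            K1 = kernel_matrix(X1, X1, hp) + 1e-8 * np.eye(16)
            y0 = 50 + 15 * (np.linalg.cholesky(K0) @ rng.standard_normal(16))
            y1 = 50 + 15 * (np.linalg.cholesky(K1) @ rng.standard_normal(16))
            st = fit_mtgp_arrays(
                np.vstack([X0, X1]), np.array([0] * 16 + [1] * 16),
                np.concatenate([y0, y1]), ["main", "aux"], n_restarts=4, seed=seed,
            )
            if abs(st.task_kernel.correlation(0, 1)) < 0.5:
                hits += 1
        assert hits >= 16

    def test_fitted_task_matrix_is_psd(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, (16, 1))
        t = np.array([0] * 8 + [1] * 8)
        y = rng.uniform(0, 100, 16)
        st = fit_mtgp_arrays(X, t, y, ["main", "aux"], n_restarts=3, seed=0)
        assert np.min(np.linalg.eigvalsh(st.task_kernel.B)) >= -1e-10


class TestTransferVariance:
    def test_unrelated_auxiliary_does_not_shrink_variance_below_similar(self):
        """With an informative (shared-function) auxiliary task the main-task
        predictive variance should be no larger, on average over seeds, than
        with an unrelated auxiliary task."""
        var_similar, var_unrelated = [], []
        Xq = np.linspace(0, 1, 25)[:, None]
        for seed in range(8):
            rng = np.random.default_rng(4000 + seed)
            f = lambda x: np.sin(5 * x)
            X0 = rng.uniform(0, 1, (3, 1))
            X1 = rng.uniform(0, 1, (25, 1))
            y0 = 50 + 20 * f(X0[:, 0])
            y1_sim = 45 + 18 * f(X1[:, 0])
            hp = KernelHyperparams(1.0, np.array([0.25]), 1e-6)
            K1 = kernel_matrix(X1, X1, hp) + 1e-8 * np.eye(25)
            y1_unrel = 50 + 15 * (np.linalg.cholesky(K1) @ rng.standard_normal(25))
            for ys, acc in [(y1_sim, var_similar), (y1_unrel, var_unrelated)]:
                st = fit_mtgp_arrays(
                    np.vstack([X0, X1]), np.array([0] * 3 + [1] * 25),
                    np.concatenate([y0, ys]), ["main", "aux"], n_restarts=4, seed=seed,
                )
                _, v = mt_posterior(st, Xq, "main", full_cov=False)
                acc.append(np.mean(v) / st.y_sds[0] ** 2)
        assert np.mean(var_unrelated) >= np.mean(var_similar)
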