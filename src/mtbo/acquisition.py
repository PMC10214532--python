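"""Acquisition functions: expected improvement and q-noisy expected improvement.

EI uses the closed form EI(x) = (mu - y*) Phi(z) + sd * phi(z) with
z = (mu - y*) / sd, where y* is the best observed yield.  It carries no
exploration jitter term.

qNEI replaces the observed incumbent with the posterior maximum over the
observed inputs: it draws joint posterior samples over (candidate batch
UNION observed inputs) and averages max(0, max over candidates - max over
observed).  This is robust to observation noise, where the best observed
value is a biased incumbent, and naturally supports batches.  The base
normal draws are fixed per seed so the acquisition surface is deterministic
for the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.stats import norm

from .gp import GPState, posterior, psd_factor
from .multitask import MultiTaskGPState, mt_posterior

__all__ = [
    "AcquisitionConfig",
    "ModelView",
    "make_view",
    "expected_improvement",
    "ei_over_candidates",
    "qnei",
]

MIN_MC_SAMPLES = 64


@dataclass(frozen=True)
class AcquisitionConfig:
    """Which acquisition to use and how to estimate it.

    kind        "EI" (closed form; the in-silico default) or "qNEI"
                (Monte Carlo; the experimental default)
    mc_samples  posterior samples for qNEI (>= 64)
    seed        base-sample seed (fixed per optimization round)
    q           batch size for qNEI
    """

    kind: str = "EI"
    mc_samples: int = 512
    seed: int = 0
    q: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("EI", "qNEI"):
            raise ValueError(f"unknown acquisition kind {self.kind!r}")
        if self.q < 1:
            raise ValueError("batch size q must be >= 1")
        if self.kind == "qNEI" and self.mc_samples < MIN_MC_SAMPLES:
            raise ValueError(f"qNEI requires mc_samples >= {MIN_MC_SAMPLES}")


@dataclass(frozen=True)
class ModelView:
    """A uniform read surface over single-task and multitask surrogates."""

    state: Union[GPState, MultiTaskGPState]
    task: Optional[str] = None

    def posterior(self, Xq: np.ndarray, full_cov: bool = False):
        if isinstance(self.state, MultiTaskGPState):
            return mt_posterior(self.state, Xq, self.task, full_cov=full_cov)
        return posterior(self.state, Xq, full_cov=full_cov)

    @property
    def observed_X(self) -> np.ndarray:
        """Observed inputs of the (target-task) observations."""
        if isinstance(self.state, MultiTaskGPState):
            return self.state.task_rows(self.task)
        return self.state.X

    @property
    def best_observed(self) -> float:
        if isinstance(self.state, MultiTaskGPState):
            return self.state.best_observed(self.task)
        return self.state.best_observed


def make_view(state: Union[GPState, MultiTaskGPState], task: Optional[str] = None) -> ModelView:
    if isinstance(state, MultiTaskGPState):
        if task is None:
            raise ValueError("a multitask state needs a target task")
        state.task_index(task)  # validates
    return ModelView(state, task)


# ---------------------------------------------------------------------------
# expected improvement


def expected_improvement(
    mean: np.ndarray, sd: np.ndarray, incumbent: float
) -> np.ndarray:
    """Closed-form EI of N(mean, sd^2) over the incumbent; elementwise."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be nonnegative")
    improve = mean - incumbent
    out = np.maximum(improve, 0.0)  # degenerate sd = 0 limit
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, improve / np.where(sd > 0, sd, 1.0), 0.0)
    pos = sd > 0
    ei = improve * norm.cdf(z) + sd * norm.pdf(z)
    return np.where(pos, ei, out) if out.ndim else float(np.where(pos, ei, out))


def ei_over_candidates(view: ModelView, Xq: np.ndarray) -> np.ndarray:
    """EI at each candidate, with y* = best observed yield (percent units)."""
    if view.observed_X.shape[0] == 0:
        raise ValueError("EI incumbent undefined: no observations")
    mean, var = view.posterior(np.atleast_2d(Xq), full_cov=False)
    return np.asarray(expected_improvement(mean, np.sqrt(var), view.best_observed))


# ---------------------------------------------------------------------------
# q-noisy expected improvement


def qnei(view: ModelView, Xcand: np.ndarray, config: AcquisitionConfig) -> float:
    """Monte-Carlo qNEI of a candidate batch against the observed inputs.

    Joint posterior samples are drawn over candidates and observed inputs
    together, so candidate/incumbent correlations are respected; each sample
    contributes max(0, max_cand - max_obs).
    """
    if config.mc_samples < MIN_MC_SAMPLES:
        raise ValueError(f"qNEI requires mc_samples >= {MIN_MC_SAMPLES}")
    Xcand = np.atleast_2d(np.asarray(Xcand, dtype=float))
    # canonical candidate order makes the estimate exactly permutation-invariant
    Xcand = Xcand[np.lexsort(Xcand.T[::-1])]
    Xobs = view.observed_X
    if Xobs.shape[0] == 0:
        raise ValueError("qNEI undefined: no observed inputs")
    q = Xcand.shape[0]
    Xjoint = np.vstack([Xcand, Xobs])
    mean, cov = view.posterior(Xjoint, full_cov=True)
    F = psd_factor(cov)
    rng = np.random.default_rng(config.seed)
    Z = rng.standard_normal((config.mc_samples, F.shape[1]))
    samples = mean[None, :] + Z @ F.T
    gain = np.max(samples[:, :q], axis=1) - np.max(samples[:, q:], axis=1)
    return float(np.mean(np.maximum(gain, 0.0)))
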