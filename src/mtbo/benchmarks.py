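"""Ground-truth yield emulators for in-silico optimization campaigns.

Two kinds of benchmark stand behind the campaign runner:

* :class:`SyntheticTaskFamily` — a parametric family of reaction-yield
  surfaces over a mixed continuous/categorical domain.  Each task's latent
  response is a blend ``rho * shared + (1 - rho) * independent_t`` of a
  family-wide surface and a task-private one, so ``rho`` tunes inter-task
  similarity from unrelated campaigns (rho = 0) to identical chemistry
  (rho = 1).  Each surface is a concave quadratic bowl per categorical
  level (per-level amplitude, per-dimension optimum location and curvature)
  pushed through a logistic squashing onto [0, 100] percent — yields
  saturate physically at both ends.  Observation noise is additive Gaussian,
  clamped back to [0, 100].

* :func:`train_table_surrogate` — a yield-predicting regression surrogate
  fit to a user-supplied experiment table, exposed as a noiseless benchmark.
  The default regressor is the in-repo Matérn GP.

The default domain mirrors a flow-chemistry catalyst screen: residence time
5-60 min, temperature 50-150 °C, catalyst loading 1-10 mol%, and an
8-level categorical catalyst.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
from scipy.optimize import minimize

from .domain import CategoricalVariable, Condition, ContinuousVariable, Domain, ExperimentTable, encode
from .gp import GPState, fit_gp, posterior

__all__ = [
    "default_domain",
    "SyntheticTaskFamily",
    "BenchmarkHandle",
    "make_task_family",
    "evaluate_yield",
    "ground_truth_optimum",
    "train_table_surrogate",
]


def default_domain(n_levels: int = 8) -> Domain:
    """The default synthetic condition space: 3 continuous + 1 categorical."""
    return Domain(
        (
            ContinuousVariable("time", 5.0, 60.0, "min"),
            ContinuousVariable("temperature", 50.0, 150.0, "degC"),
            ContinuousVariable("catalyst_loading", 1.0, 10.0, "mol%"),
            CategoricalVariable("catalyst", tuple(f"C{i + 1}" for i in range(n_levels))),
        ),
        objective_name="yield",
        maximize=True,
    )


@dataclass(frozen=True)
class _Surface:
    """One latent response: amp[level] - sum_j w_j (z_j - opt_j)^2."""

    amp: np.ndarray  # (n_levels,) per-level amplitude
    opt: np.ndarray  # (ncont,) optimum location in [0,1] coordinates
    curvature: np.ndarray  # (ncont,) positive

    def latent(self, Z: np.ndarray, level_idx: np.ndarray) -> np.ndarray:
        bowl = np.sum(self.curvature[None, :] * (Z - self.opt[None, :]) ** 2, axis=1)
        return self.amp[level_idx] - bowl


# logistic squashing of the latent response onto percent yields
_SQUASH_SCALE = 1.0
_SQUASH_SHIFT = 0.5


def _squash(latent: np.ndarray) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(-(_SQUASH_SCALE * latent + _SQUASH_SHIFT)))


@dataclass(frozen=True)
class BenchmarkHandle:
    """A callable ground truth the campaign runner can query."""

    domain: Domain
    noiseless: Callable[[Condition], float]
    noise_sd: float
    provenance: str  # "synthetic" | "table-surrogate"
    truth: Optional[tuple[Condition, float]] = None

    def evaluate(self, condition: Condition, rng: Optional[np.random.Generator] = None) -> float:
        y = self.noiseless(condition)
        if self.noise_sd > 0 and rng is not None:
            y += self.noise_sd * rng.standard_normal()
        return float(np.clip(y, 0.0, 100.0))


@dataclass(frozen=True)
class SyntheticTaskFamily:
    """A reproducible family of related reaction-yield surfaces."""

    domain: Domain
    n_tasks: int
    rho: float
    noise_sd: float
    seed: int
    shared: _Surface = field(repr=False, default=None)
    independent: tuple[_Surface, ...] = field(repr=False, default=None)

    @property
    def ncont(self) -> int:
        return len(self.domain.continuous)

    @property
    def n_levels(self) -> int:
        cats = self.domain.categorical
        return len(cats[0].levels) if cats else 1

    # -- evaluation --------------------------------------------------------
    def _blend(self, task: int) -> _Surface:
        """The task's effective surface: still amplitude + concave quadratic."""
        if not (0 <= task < self.n_tasks):
            raise ValueError(f"unknown task index {task}; family has {self.n_tasks} tasks")
        r, s, g = self.rho, self.shared, self.independent[task]
        w = r * s.curvature + (1.0 - r) * g.curvature
        opt = (r * s.curvature * s.opt + (1.0 - r) * g.curvature * g.opt) / w
        # constant left over after completing the square, folded into amp
        const = (
            r * np.sum(s.curvature * s.opt**2)
            + (1.0 - r) * np.sum(g.curvature * g.opt**2)
            - np.sum(w * opt**2)
        )
        amp = r * s.amp + (1.0 - r) * g.amp - const
        return _Surface(amp, opt, w)

    def _zl(self, condition: Condition) -> tuple[np.ndarray, int]:
        vec = encode(condition, self.domain)
        z = vec[: self.ncont]
        if self.domain.categorical:
            block = vec[self.ncont :]
            level = int(np.argmax(block))
        else:
            level = 0
        return z, level

    def noiseless_yield(self, task: int, condition: Condition) -> float:
        z, level = self._zl(condition)
        surf = self._blend(task)
        return float(_squash(surf.latent(z[None, :], np.array([level])))[0])

    def noiseless_batch(self, task: int, Z: np.ndarray, level_idx: np.ndarray) -> np.ndarray:
        """Vectorized noiseless yields at [0,1]-coordinates and level indices."""
        surf = self._blend(task)
        return _squash(surf.latent(np.atleast_2d(Z), np.asarray(level_idx, dtype=int)))

    def analytic_optimum(self, task: int) -> tuple[Condition, float]:
        """Exact argmax: the blended surface stays a concave quadratic per level."""
        surf = self._blend(task)
        level = int(np.argmax(surf.amp))
        z = np.clip(surf.opt, 0.0, 1.0)
        values: dict = {}
        for j, v in enumerate(self.domain.continuous):
            values[v.name] = v.lower + z[j] * (v.upper - v.lower)
        if self.domain.categorical:
            cat = self.domain.categorical[0]
            values[cat.name] = cat.levels[level]
        cond = Condition.from_mapping(values)
        return cond, self.noiseless_yield(task, cond)

    def handle(self, task: int) -> BenchmarkHandle:
        return BenchmarkHandle(
            domain=self.domain,
            noiseless=lambda c, _t=task: self.noiseless_yield(_t, c),
            noise_sd=self.noise_sd,
            provenance="synthetic",
            truth=self.analytic_optimum(task),
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "domain": self.domain.to_dict(),
            "n_tasks": self.n_tasks,
            "rho": self.rho,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTaskFamily":
        return make_task_family(
            n_tasks=int(d["n_tasks"]),
            rho=float(d["rho"]),
            noise_sd=float(d["noise_sd"]),
            seed=int(d["seed"]),
            domain=Domain.from_dict(d["domain"]),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTaskFamily":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_task_family(
    n_tasks: int,
    rho: float,
    noise_sd: float = 2.0,
    seed: int = 0,
    domain: Optional[Domain] = None,
) -> SyntheticTaskFamily:
    """Draw a seeded family of ``n_tasks`` related yield surfaces.

    ``rho`` in [0, 1] is the fraction of each task's surface taken from the
    family-shared component; the remainder is task-private.  Surfaces are
    byte-identical functions of (parameters, seed).
    """
    if n_tasks < 1:
        raise ValueError("need n_tasks >= 1")
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if domain is None:
        domain = default_domain()
    rng = np.random.default_rng(seed)
    ncont = len(domain.continuous)
    cats = domain.categorical
    n_levels = len(cats[0].levels) if cats else 1
    if len(cats) > 1:
        raise ValueError("synthetic families support at most one categorical variable")

    def draw_surface() -> _Surface:
        return _Surface(
            amp=rng.normal(0.0, 0.8, n_levels),
            opt=rng.uniform(0.15, 0.85, ncont),
            curvature=rng.uniform(1.0, 3.0, ncont),
        )

    shared = draw_surface()
    independent = tuple(draw_surface() for _ in range(n_tasks))
    return SyntheticTaskFamily(domain, n_tasks, rho, noise_sd, seed, shared, independent)


def evaluate_yield(
    family: SyntheticTaskFamily,
    task: int,
    condition: Condition,
    noisy: bool = False,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Query one yield; ``noisy`` adds N(0, noise_sd^2) then clamps to [0, 100]."""
    y = family.noiseless_yield(task, condition)
    if noisy and family.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y += family.noise_sd * rng.standard_normal()
    return float(np.clip(y, 0.0, 100.0))


def ground_truth_optimum(
    family: SyntheticTaskFamily, task: int, grid_density: int = 21
) -> tuple[Condition, float]:
    """Dense-grid argmax over levels x continuous grid, with local refinement.

    The refined optimum never falls below the grid incumbent.
    """
    ncont = family.ncont
    axes = [np.linspace(0.0, 1.0, grid_density)] * ncont
    if ncont:
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, ncont)
    else:
        mesh = np.zeros((1, 0))
    best_val, best_z, best_level = -np.inf, None, 0
    for level in range(family.n_levels):
        vals = family.noiseless_batch(task, mesh, np.full(mesh.shape[0], level))
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val, best_z, best_level = float(vals[i]), mesh[i], level

    if ncont:
        def neg(z: np.ndarray) -> float:
            return -float(family.noiseless_batch(task, z[None, :], [best_level])[0])

        res = minimize(neg, best_z, method="L-BFGS-B", bounds=[(0.0, 1.0)] * ncont)
        if -res.fun > best_val:
            best_val, best_z = -float(res.fun), np.clip(res.x, 0.0, 1.0)

    values: dict = {}
    for j, v in enumerate(family.domain.continuous):
        values[v.name] = v.lower + best_z[j] * (v.upper - v.lower)
    if family.domain.categorical:
        cat = family.domain.categorical[0]
        values[cat.name] = cat.levels[best_level]
    return Condition.from_mapping(values), best_val


def train_table_surrogate(
    table: ExperimentTable, n_restarts: int = 8, seed: int = 0
) -> BenchmarkHandle:
    """Fit a GP yield emulator to an experiment table (>= 20 rows).

    The handle is noiseless: it returns the posterior-mean yield clamped to
    [0, 100], playing the ground-truth role in simulated campaigns.
    """
    if len(table) < 20:
        raise ValueError(f"surrogate training needs >= 20 observations, got {len(table)}")
    state = fit_gp(table, n_restarts=n_restarts, seed=seed)
    domain = table.domain

    def predict(condition: Condition) -> float:
        mean, _ = posterior(state, encode(condition, domain)[None, :], full_cov=False)
        return float(np.clip(mean[0], 0.0, 100.0))

    return BenchmarkHandle(domain=domain, noiseless=predict, noise_sd=0.0, provenance="table-surrogate")
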