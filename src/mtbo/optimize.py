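"""Latin hypercube designs and acquisition maximization over mixed spaces.

Categorical variables are handled by exact enumeration of level combinations
(sampled uniformly without replacement if their product exceeds a cap); for
each combination the acquisition is maximized over the continuous block by
multi-start bounded L-BFGS-B seeded from a scrambled LHS.  The relaxed
one-hot representation is never returned: every candidate evaluated carries
an exact indicator block, so the returned condition is always valid under
the domain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .acquisition import AcquisitionConfig, ModelView, ei_over_candidates, qnei
from .domain import Condition, Domain, decode

__all__ = ["OptimizerConfig", "lhs_design", "maximize_acquisition"]


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs for the acquisition maximizer.

    n_restarts        L-BFGS-B starts per categorical combination
    n_presample       LHS points screened per combination to pick the starts
    max_combinations  cap on enumerated categorical combinations
    seed              randomness for starts / combination subsampling
    tol               duplicate-suppression radius on encoded vectors
    """

    n_restarts: int = 8
    n_presample: int = 64
    max_combinations: int = 64
    seed: int = 0
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.n_presample < 1 or self.max_combinations < 1:
            raise ValueError("optimizer caps must be positive")


# ---------------------------------------------------------------------------
# Latin hypercube design


def lhs_design(domain: Domain, n: int, seed: int = 0) -> list[Condition]:
    """n space-filling conditions: scrambled LHS on the continuous block
    (exactly one sample per equal-probability stratum per dimension) and
    stratified level cycling, shuffled, on each categorical variable."""
    if n < 1:
        raise ValueError("LHS design needs n >= 1")
    rng = np.random.default_rng(seed)
    ncont = len(domain.continuous)
    if ncont:
        sampler = qmc.LatinHypercube(d=ncont, scramble=True, seed=rng)
        Z = sampler.random(n)
    else:
        Z = np.empty((n, 0))
    conditions = []
    cat_assignments = {}
    for v in domain.categorical:
        levels = [v.levels[i % len(v.levels)] for i in range(n)]
        rng.shuffle(levels)
        cat_assignments[v.name] = levels
    for i in range(n):
        values: dict = {}
        for j, v in enumerate(domain.continuous):
            values[v.name] = v.lower + Z[i, j] * (v.upper - v.lower)
        for v in domain.categorical:
            values[v.name] = cat_assignments[v.name][i]
        conditions.append(Condition.from_mapping(values))
    return conditions


# ---------------------------------------------------------------------------
# acquisition maximization


def _combinations(domain: Domain, config: OptimizerConfig) -> list[tuple[int, ...]]:
    sizes = [len(v.levels) for v in domain.categorical]
    total = int(np.prod(sizes)) if sizes else 1
    combos = list(itertools.product(*[range(s) for s in sizes]))
    if total > config.max_combinations:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(total, size=config.max_combinations, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    return combos


def _onehot_tail(domain: Domain, combo: tuple[int, ...]) -> np.ndarray:
    blocks = []
    for v, idx in zip(domain.categorical, combo):
        b = np.zeros(len(v.levels))
        b[idx] = 1.0
        blocks.append(b)
    return np.concatenate(blocks) if blocks else np.empty(0)


def _acq_function(
    view: ModelView, acq: AcquisitionConfig
) -> Callable[[np.ndarray], np.ndarray]:
    if acq.kind == "EI":
        return lambda X: ei_over_candidates(view, X)
    return lambda X: np.array([qnei(view, x[None, :], acq) for x in np.atleast_2d(X)])


def maximize_acquisition(
    view: ModelView,
    domain: Domain,
    acq_config: AcquisitionConfig,
    opt_config: OptimizerConfig,
    avoid: Optional[Sequence[np.ndarray]] = None,
) -> tuple[Condition, float]:
    """Global acquisition argmax over the mixed domain.

    ``avoid`` lists encoded vectors of already-run conditions; if the argmax
    falls within ``tol`` (max-norm) of one, the best evaluated non-duplicate
    candidate is returned instead, so noise-free campaigns cannot stall by
    re-suggesting their incumbent.  Deterministic given (view, seeds).
    """
    acq_fn = _acq_function(view, acq_config)
    ncont = len(domain.continuous)
    combos = _combinations(domain, opt_config)
    rng = np.random.default_rng(opt_config.seed)

    evaluated: list[tuple[float, np.ndarray]] = []
    for combo in combos:
        tail = _onehot_tail(domain, combo)
        if ncont == 0:
            vec = tail
            evaluated.append((float(acq_fn(vec[None, :])[0]), vec))
            continue
        sampler = qmc.LatinHypercube(d=ncont, scramble=True, seed=rng)
        Z0 = sampler.random(opt_config.n_presample)
        cand = np.hstack([Z0, np.tile(tail, (Z0.shape[0], 1))])
        vals = np.asarray(acq_fn(cand))
        for z, v in zip(Z0, vals):
            evaluated.append((float(v), np.concatenate([z, tail])))
        order = np.argsort(-vals)[: opt_config.n_restarts]

        def neg(z: np.ndarray) -> float:
            x = np.concatenate([z, tail])
            return -float(acq_fn(x[None, :])[0])

        for i in order:
            res = minimize(
                neg, Z0[i], method="L-BFGS-B", bounds=[(0.0, 1.0)] * ncont, options={"maxiter": 50}
            )
            z = np.clip(res.x, 0.0, 1.0)
            evaluated.append((-float(res.fun), np.concatenate([z, tail])))

    if not evaluated:
        raise ValueError("empty domain: nothing to optimize over")

    # sort best-first; ties broken by lexicographically smallest encoded vector
    evaluated.sort(key=lambda t: (-t[0], tuple(t[1])))
    avoid_arr = np.atleast_2d(np.asarray(avoid)) if avoid is not None and len(avoid) else None

    def is_duplicate(vec: np.ndarray) -> bool:
        if avoid_arr is None:
            return False
        return bool(np.any(np.max(np.abs(avoid_arr - vec[None, :]), axis=1) <= opt_config.tol))

    best_val, best_vec = evaluated[0]
    if is_duplicate(best_vec):
        for val, vec in evaluated[1:]:
            if not is_duplicate(vec):
                best_val, best_vec = val, vec
                break
        # if literally everything is a duplicate, fall through with the argmax
    return decode(best_vec, domain, categorical="strict"), float(best_val)
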