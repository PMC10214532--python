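"""Closed-loop optimization campaigns: STBO, MTBO, repeats and summaries.

A campaign alternates (fit surrogate on everything observed so far ->
maximize the acquisition -> run the suggested experiment -> append) until
the experiment budget is spent.  STBO fits a single-task GP and seeds itself
with a Latin-hypercube design; MTBO fits the ICM multitask GP jointly on the
main table plus frozen auxiliary campaign tables and, when auxiliary data
exist, starts suggesting from experiment 1 with no initialization phase.

For the very first MTBO suggestion the main task has no observations yet, so
no joint model involving it is identifiable; that one suggestion comes from
a single-task GP pooled over the auxiliary data with the best auxiliary
yield as incumbent — i.e. the algorithm begins near the best previously
known conditions and corrects from the first main-task measurement onward.

All randomness derives from the campaign seed through a seed tree, so runs
against noiseless benchmarks are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, make_view
from .benchmarks import BenchmarkHandle
from .domain import CategoricalVariable, Condition, Domain, ExperimentTable, Observation, encode
from .gp import fit_gp
from .multitask import fit_mtgp
from .optimize import OptimizerConfig, lhs_design, maximize_acquisition

__all__ = [
    "MAIN_TASK",
    "CampaignConfig",
    "IterationRecord",
    "CampaignResult",
    "ComparisonSummary",
    "run_campaign",
    "suggest_next",
    "compare_strategies",
    "experiments_to_optimum",
    "selection_frequency",
]

MAIN_TASK = "main"
NOT_REACHED = -1  # sentinel for experiments_to_optimum


@dataclass(frozen=True)
class CampaignConfig:
    """Everything needed to (re)run one campaign.

    strategy          "STBO" or "MTBO"
    budget            number of algorithm-suggested experiments
    n_init            LHS initialization experiments; forced to 0 for MTBO
                      with auxiliary data (prior information replaces it)
    auxiliary_tables  frozen auxiliary-campaign tables (MTBO only)
    """

    strategy: str = "STBO"
    budget: int = 20
    n_init: int = 8
    auxiliary_tables: tuple[ExperimentTable, ...] = ()
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0
    fit_restarts: int = 3  # per-iteration refits; standalone fits default to 8

    def __post_init__(self) -> None:
        if self.strategy not in ("STBO", "MTBO"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.strategy == "STBO" and self.auxiliary_tables:
            raise ValueError("STBO takes no auxiliary tables")
        object.__setattr__(self, "auxiliary_tables", tuple(self.auxiliary_tables))
        if self.strategy == "MTBO" and self.auxiliary_tables and self.n_init != 0:
            object.__setattr__(self, "n_init", 0)
        if self.strategy == "STBO" and self.n_init < 2:
            raise ValueError("STBO needs n_init >= 2 to fit its first model")


@dataclass(frozen=True)
class IterationRecord:
    index: int  # 1-based over all executed experiments
    phase: str  # "init" | "suggest"
    condition: Condition
    yield_observed: float
    yield_noiseless: Optional[float] = None
    acq_value: Optional[float] = None
    model_info: Optional[dict] = None


@dataclass
class CampaignResult:
    config: CampaignConfig
    iterations: list[IterationRecord]
    best_trajectory: np.ndarray  # best-so-far observed yield per experiment
    error: Optional[str] = None

    @property
    def n_experiments(self) -> int:
        return len(self.iterations)

    def main_table(self, domain: Domain) -> ExperimentTable:
        return ExperimentTable(
            domain,
            [Observation(r.condition, float(np.clip(r.yield_observed, 0, 100)), MAIN_TASK) for r in self.iterations],
        )

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for r, b in zip(self.iterations, self.best_trajectory):
            row = {"experiment": r.index, "phase": r.phase}
            row.update(r.condition.as_dict())
            row["yield"] = r.yield_observed
            row["best_so_far"] = b
            if r.acq_value is not None:
                row["acq_value"] = r.acq_value
            rows.append(row)
        return pd.DataFrame(rows)


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _aux_merged(domain: Domain, tables: Sequence[ExperimentTable]) -> ExperimentTable:
    obs = []
    for k, t in enumerate(tables):
        if t.domain.to_dict() != domain.to_dict():
            raise ValueError("auxiliary table domain does not match the benchmark domain")
        for o in t.observations:
            obs.append(Observation(o.condition, o.yield_pct, f"aux{k}" if o.task == MAIN_TASK else o.task))
    return ExperimentTable(domain, obs)


def _fit_and_suggest(
    domain: Domain,
    main: ExperimentTable,
    config: CampaignConfig,
    iteration: int,
) -> tuple[Condition, float, dict]:
    """One model fit + acquisition maximization; shared by run and live modes."""
    seeds = _derive_seeds(config.seed, 4 + 2 * (iteration + 1))
    fit_seed, acq_seed = seeds[-2], seeds[-1]
    acq = replace(config.acquisition, seed=acq_seed)
    opt = replace(config.optimizer, seed=acq_seed)

    if config.strategy == "MTBO" and config.auxiliary_tables:
        aux = _aux_merged(domain, config.auxiliary_tables)
        if len(main) == 0:
            # cold start: exploit pooled auxiliary knowledge (see module docstring)
            pooled = fit_gp(aux, n_restarts=config.fit_restarts, seed=fit_seed)
            view = make_view(pooled)
            info = {"model": "pooled-aux-gp", "n_train": len(aux)}
        else:
            joint = main.merged_with([aux])
            labels = [MAIN_TASK] + [l for l in joint.task_labels if l != MAIN_TASK]
            state = fit_mtgp(joint, n_restarts=config.fit_restarts, seed=fit_seed, task_labels=labels)
            view = make_view(state, MAIN_TASK)
            info = {
                "model": "icm-mtgp",
                "n_train": len(joint),
                "task_correlations": [
                    round(state.task_kernel.correlation(0, i), 4) for i in range(1, state.n_tasks)
                ],
            }
    else:
        state = fit_gp(main, n_restarts=config.fit_restarts, seed=fit_seed)
        view = make_view(state)
        info = {"model": "gp", "n_train": len(main)}

    avoid = [encode(o.condition, domain) for o in main.observations]
    cond, value = maximize_acquisition(view, domain, acq, opt, avoid=avoid)
    return cond, value, info


def run_campaign(benchmark: BenchmarkHandle, config: CampaignConfig) -> CampaignResult:
    """Run one closed-loop campaign against a benchmark."""
    domain = benchmark.domain
    for t in config.auxiliary_tables:
        if t.domain.to_dict() != domain.to_dict():
            raise ValueError("auxiliary table domain does not match the benchmark domain")
    seeds = _derive_seeds(config.seed, 2)
    noise_rng = np.random.default_rng(seeds[0])
    records: list[IterationRecord] = []
    error = None

    def observe(cond: Condition, phase: str, acq_value: Optional[float], info: Optional[dict]) -> None:
        y = benchmark.evaluate(cond, rng=noise_rng)
        records.append(
            IterationRecord(
                index=len(records) + 1,
                phase=phase,
                condition=cond,
                yield_observed=y,
                yield_noiseless=float(benchmark.noiseless(cond)),
                acq_value=acq_value,
                model_info=info,
            )
        )

    for cond in lhs_design(domain, config.n_init, seed=seeds[1]) if config.n_init > 0 else []:
        observe(cond, "init", None, None)

    main = ExperimentTable(domain, [])
    for i in range(config.budget):
        main = ExperimentTable(
            domain, [Observation(r.condition, r.yield_observed, MAIN_TASK) for r in records]
        )
        try:
            cond, value, info = _fit_and_suggest(domain, main, config, i)
        except (np.linalg.LinAlgError, ValueError) as err:
            error = f"iteration {i + 1}: {err}"
            break
        observe(cond, "suggest", value, info)

    best = np.maximum.accumulate([r.yield_observed for r in records]) if records else np.empty(0)
    return CampaignResult(config, records, np.asarray(best, dtype=float), error)


def suggest_next(
    domain: Domain,
    main_table: ExperimentTable,
    config: CampaignConfig,
) -> Condition:
    """Live mode: the next experiment to run, given everything measured so far.

    Returns the ``len(main_table)``-th point of the seeded LHS design while
    initialization is pending, otherwise the acquisition argmax.  Idempotent
    for fixed inputs and seed.
    """
    seeds = _derive_seeds(config.seed, 2)
    use_lhs = config.n_init > 0 and not (config.strategy == "MTBO" and config.auxiliary_tables)
    if use_lhs and len(main_table) < config.n_init:
        return lhs_design(domain, config.n_init, seed=seeds[1])[len(main_table)]
    cond, _, _ = _fit_and_suggest(domain, main_table, config, iteration=len(main_table))
    return cond


# ---------------------------------------------------------------------------
# aggregation over repeats


@dataclass
class ComparisonSummary:
    """Aggregated repeat-run statistics per strategy."""

    n_repeats: int
    results: dict[str, list[CampaignResult]]
    mean_trajectory: dict[str, np.ndarray]
    ci_halfwidth: dict[str, np.ndarray]  # 1.96 * sd / sqrt(n_repeats)
    selection_frequencies: dict[str, dict[str, dict[str, float]]]  # strategy -> var -> level -> frac

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for name, mean in self.mean_trajectory.items():
            ci = self.ci_halfwidth[name]
            for i, (m, c) in enumerate(zip(mean, ci)):
                rows.append({"strategy": name, "experiment": i + 1, "mean_best_yield": m, "ci95_halfwidth": c})
        return pd.DataFrame(rows)

    def frequency_frame(self) -> pd.DataFrame:
        rows = []
        for name, per_var in self.selection_frequencies.items():
            for var, freqs in per_var.items():
                for level, frac in freqs.items():
                    rows.append({"strategy": name, "variable": var, "level": level, "frequency": frac})
        return pd.DataFrame(rows)


def compare_strategies(
    benchmark: BenchmarkHandle,
    configs: dict[str, CampaignConfig],
    n_repeats: int = 20,
    base_seed: int = 0,
) -> ComparisonSummary:
    """Run each configuration ``n_repeats`` times with derived seeds and
    aggregate mean best-yield trajectories, 95% CIs and selection frequencies."""
    if n_repeats < 2:
        raise ValueError("need n_repeats >= 2")
    cat_vars = [v.name for v in benchmark.domain.categorical]

    results: dict[str, list[CampaignResult]] = {}
    mean_traj: dict[str, np.ndarray] = {}
    ci: dict[str, np.ndarray] = {}
    freqs: dict[str, dict[str, dict[str, float]]] = {}
    repeat_seeds = _derive_seeds(base_seed, n_repeats)
    for name, config in configs.items():
        runs = [
            run_campaign(benchmark, replace(config, seed=repeat_seeds[r])) for r in range(n_repeats)
        ]
        results[name] = runs
        n = min(len(r.best_trajectory) for r in runs)
        stack = np.stack([r.best_trajectory[:n] for r in runs])
        mean_traj[name] = stack.mean(axis=0)
        ci[name] = 1.96 * stack.std(axis=0, ddof=1) / np.sqrt(n_repeats)
        freqs[name] = {v: selection_frequency(runs, v, benchmark.domain) for v in cat_vars}
    return ComparisonSummary(n_repeats, results, mean_traj, ci, freqs)


def experiments_to_optimum(
    result: CampaignResult, truth_yield: float, tol_pct: float = 1.0
) -> int:
    """1-based index of the first experiment whose noiseless yield reaches
    ``truth_yield - tol_pct``; ``NOT_REACHED`` (-1) if none does."""
    for r in result.iterations:
        y = r.yield_noiseless if r.yield_noiseless is not None else r.yield_observed
        if y >= truth_yield - tol_pct:
            return r.index
    return NOT_REACHED


def selection_frequency(
    results: Sequence[CampaignResult],
    variable: str,
    domain: Optional[Domain] = None,
) -> dict[str, float]:
    """How often each level of a categorical variable was suggested,
    pooled over all algorithm-suggested (non-initialization) experiments.

    With ``domain`` given, unselected levels appear with frequency 0.0 and
    the variable is checked to be categorical.
    """
    if not results:
        raise ValueError("no results to pool")
    counts: dict[str, int] = {}
    if domain is not None:
        var = domain.variable(variable)
        if not isinstance(var, CategoricalVariable):
            raise ValueError(f"variable {variable!r} is not categorical")
        counts = {level: 0 for level in var.levels}
    else:
        sample = results[0].iterations[0].condition.as_dict() if results[0].iterations else {}
        if variable not in sample:
            raise ValueError(f"unknown variable {variable!r}")
    total = 0
    for r in results:
        for it in r.iterations:
            if it.phase != "suggest":
                continue
            level = it.condition[variable]
            if not isinstance(level, str):
                raise ValueError(f"variable {variable!r} is not categorical")
            counts[level] = counts.get(level, 0) + 1
            total += 1
    if total == 0:
        return {level: 0.0 for level in counts}
    return {level: c / total for level, c in counts.items()}
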