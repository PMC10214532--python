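# mtbo — multitask Bayesian optimization of reaction conditions

`mtbo` is a Python toolkit for optimizing chemical reaction conditions —
mixed spaces of continuous variables (residence time, temperature, catalyst
loading) and categorical variables (solvent, ligand, catalyst) — for
percent yield under tight experiment budgets, as in flow-chemistry
self-optimization and fragment-based drug discovery, where material for
each experiment is scarce.

Its core idea is **transfer learning across optimization campaigns**.
Single-task Bayesian optimization (STBO) models the current reaction with a
Gaussian process,

  y(x) ~ GP(0, k(x, x′)),  k = σ²(1 + √5 d + 5d²/3) e^(−√5 d),
  d² = Σⱼ ((xⱼ − x′ⱼ)/Lⱼ)²,

and picks the next experiment by maximizing expected improvement
EI(x) = (μ − y*)Φ(z) + σ̃φ(z) (or its noise-robust Monte-Carlo variant
qNEI for real experiments). Multitask Bayesian optimization (MTBO)
replaces the GP with an intrinsic coregionalization model trained jointly
on the current campaign and completed campaigns of related substrates:

  cov[(x, t), (x′, t′)] = B[t, t′] · k(x, x′),  B = AAᵀ + diag(exp(c)),

where the T×T task matrix B learns inter-task correlations. When the
auxiliary chemistry is similar, MTBO starts from the best previously known
conditions instead of a space-filling design and reaches the optimum in
fewer experiments.

The package provides: condition-space declaration and one-hot/min–max
encoding, exact GP and multitask-GP regression with marginal-likelihood
training, EI/qNEI acquisition with a mixed-space maximizer, Latin-hypercube
initialization, a closed-loop campaign runner with repeat-run statistics,
and a synthetic reaction-yield benchmark family with tunable inter-task
correlation for fully offline in-silico studies.

## Worked example

Compare STBO against MTBO on a synthetic two-task family whose tasks share
80% of their chemistry (ρ = 0.8), with a 96-point auxiliary campaign:

```python
import numpy as np
from mtbo import (CampaignConfig, ExperimentTable, Observation,
                  experiments_to_optimum, lhs_design, make_task_family,
                  run_campaign)

family = make_task_family(n_tasks=2, rho=0.8, noise_sd=2.0, seed=1)
handle = family.handle(0)                      # task 0 is the "new" reaction
truth = family.analytic_optimum(0)[1]          # ground-truth best yield

aux = ExperimentTable(family.domain, [         # a finished campaign on task 1
    Observation(c, float(np.clip(family.noiseless_yield(1, c), 0, 100)), "aux0")
    for c in lhs_design(family.domain, 96, seed=99)])

mtbo = run_campaign(handle, CampaignConfig(
    strategy="MTBO", budget=20, auxiliary_tables=(aux,), seed=5))
stbo = run_campaign(handle, CampaignConfig(
    strategy="STBO", budget=20, n_init=8, seed=5))

print(f"truth {truth:.1f}%")
print("MTBO best", round(mtbo.best_trajectory[-1], 1),
      "reached 95% of optimum at experiment",
      experiments_to_optimum(mtbo, 0.95 * truth, tol_pct=0.0))
print("STBO best", round(stbo.best_trajectory[-1], 1),
      "reached 95% of optimum at experiment",
      experiments_to_optimum(stbo, 0.95 * truth, tol_pct=0.0))
```

Output:

```
truth 72.6%
MTBO best 70.6 reached 95% of optimum at experiment 10
STBO best 70.1 reached 95% of optimum at experiment -1
```

The ground-truth optimum of this family is 72.6% yield. MTBO, warm-started
by the auxiliary campaign, passes 95% of that optimum at its 10th
experiment; STBO spends 8 experiments on initialization alone and has not
reached the 95% band within its 28 experiments (−1 is the not-reached
sentinel). `compare_strategies` repeats such runs and aggregates mean
best-yield trajectories with 95% confidence intervals and
catalyst-selection frequencies.

The same workflows are scriptable from a shell (`mtbo suggest`,
`mtbo simulate`, `mtbo compare`, `mtbo make-family`, `mtbo truth`); every
command appends a manifest line so noiseless runs can be reproduced
exactly. Live campaigns use `mtbo suggest` with a domain JSON and
experiment CSVs and print the next condition to run.

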