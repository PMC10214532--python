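# Methods

## Problem setting

`mtbo` optimizes chemical reaction conditions — mixed spaces of continuous
variables (residence time, temperature, catalyst loading, ...) and
categorical variables (solvent, ligand, catalyst) — for percent yield, under
tight experiment budgets. Two closed-loop strategies are provided:

* **STBO** (single-task Bayesian optimization): a Gaussian-process surrogate
  is trained on the current campaign only, seeded by a Latin-hypercube
  design.
* **MTBO** (multitask Bayesian optimization): the surrogate is an intrinsic
  coregionalization model (ICM) trained jointly on the current campaign and
  one or more completed auxiliary campaigns from the same reaction class
  (different substrates). When auxiliary data exist there is no
  initialization phase — the algorithm suggests informative conditions from
  experiment 1.

## Encodings

Continuous variables are min–max scaled to [0, 1] by their declared bounds;
categorical variables are one-hot encoded in declared level order. The
scaling puts all dimensions on a common scale so one set of length-scale
bounds is sensible; it is a package choice, not a property of the
underlying method. Task identity is metadata, not an input feature: it
enters only through the task kernel.

## Single-task GP

Zero prior mean on standardized outputs; Matérn 5/2 kernel
k(x, x′) = σ²(1 + √5·d + 5d²/3)·exp(−√5·d) over the ARD-weighted distance
d² = Σⱼ((xⱼ − x′ⱼ)/Lⱼ)². A trainable Gaussian observation-noise variance
σₙ² (floor 10⁻⁶ on standardized units) is included: measured yields are
noisy, and the noisy-expected-improvement acquisition presupposes a noise
model. Outputs are standardized per fit (mean 0, sd 1); every user-facing
prediction is de-standardized back to percent.

Hyperparameters maximize the log marginal likelihood over log-transformed
parameters with analytic gradients (L-BFGS-B, bounds L ∈ [10⁻³, 10³] on
encoded inputs, σ² ∈ [10⁻⁸, 10⁴], σₙ² ∈ [10⁻⁶, 10²]), from 8 restarts by
default: one fixed moderate start plus randomized starts. Per-iteration
refits inside a campaign use 3 restarts — the data change by one point per
iteration and the fixed start keeps refits stable, so the extra restarts
buy little there.

Numerics: jitter 10⁻⁶·σ² is added to the covariance diagonal before
Cholesky factorization, escalating ×10 up to 10⁻²·(mean diagonal); a
failure past that is raised, never hidden. Posterior covariances are
symmetrized as (C + Cᵀ)/2 and, before joint sampling, negative eigenvalues
are clipped at zero.

## Multitask GP (ICM)

Joint covariance between observations (x, t) and (x′, t′) is
B[t, t′]·k(x, x′) with a unit-variance Matérn 5/2 input kernel shared by all
tasks. B = A·Aᵀ + diag(exp(c)) with rank(A) = min(T, 2) by default, so B is
positive semidefinite for every reachable parameter setting; the normalized
off-diagonals of B are the learned inter-task correlations. Fixing the
input signal variance at 1 removes the σ²·B scale ambiguity. Outputs are
standardized per task (auxiliary campaigns may occupy different yield
regimes); a task with fewer than two points, or with degenerate spread,
falls back to the pooled constants. All tasks share one noise variance and
one set of length scales; task-kernel rank, per-task standardization and
shared noise are configuration defaults, not claims about the underlying
method.

Auxiliary tables are frozen: only the main task accrues data during a
campaign.

## Acquisition functions

**EI** (the in-silico default): EI(x) = (μ − y*)Φ(z) + σ̃φ(z) with
z = (μ − y*)/σ̃ and y* the best observed yield; no exploration-jitter term.
The σ̃ = 0 limit is max(μ − y*, 0).

**qNEI** (the experimental default): joint posterior samples are drawn over
the candidate batch together with all observed (target-task) inputs, and
the acquisition is the Monte-Carlo mean of max(0, max over candidate
samples − max over observed-input samples). Because the incumbent is the
posterior maximum at the observed inputs *inside each sample*, the
estimate is robust to observation noise. Base normal draws are fixed per
optimization round so the surface is deterministic for the optimizer;
candidates are put in a canonical order before factorization, which makes
the value exactly permutation-invariant. Defaults: 512 samples during
optimization, 4096 in verification studies; a minimum of 64 is enforced.

## Acquisition maximization

Categorical level combinations are enumerated exactly when their product is
within a cap (default 64; the 5-solvent × 4-ligand space has 20), otherwise
sampled uniformly without replacement. Per combination, the continuous
block is maximized by bounded L-BFGS-B from the best 8 of 64 scrambled-LHS
screening points. The relaxed one-hot representation is never returned;
ties break toward the lexicographically smallest encoded vector; an argmax
within `tol` of an already-run condition is replaced by the best
non-duplicate candidate evaluated, so noise-free campaigns cannot stall on
their incumbent.

## Latin hypercube initialization

Continuous block: scrambled LHS (exactly one sample per equal-probability
stratum per dimension). Categorical variables: levels cycled to length n
then shuffled, so counts differ by at most one. The experimental protocol
default is 16 initialization experiments; in-silico comparison baselines
default to 8 (the baseline initialization size is not pinned by the
protocol and is configurable).

## Campaigns, seeds, first MTBO suggestion

A campaign iterates fit → maximize acquisition → run experiment → append.
All randomness (LHS, benchmark noise, restart initializations, Monte-Carlo
base samples) derives from the campaign seed via a seed tree, so runs
against noiseless benchmarks are exactly reproducible.

With auxiliary data present, the very first MTBO suggestion has zero
main-task observations, and the main task's rows of the ICM likelihood are
then empty — its correlations are unidentifiable. That one suggestion is
therefore produced from a single-task GP pooled over the auxiliary data,
with the best auxiliary yield as incumbent: the campaign starts near the
best previously known conditions and corrects from the first main-task
measurement onward. From experiment 2 the joint ICM model is used.

`experiments_to_optimum` counts every executed experiment (initialization
included) in 1-based order: initialization experiments are experiments a
chemist pays for. Repeat-run summaries report mean best-yield trajectories
with 95% confidence intervals computed as mean ± 1.96·sd/√n (one CI
construction among several reasonable ones), and categorical selection
frequencies pooled over algorithm-suggested experiments only.

## Synthetic benchmark family

The in-silico testbed emulates yield-predicting reaction emulators without
external data. A family over the default domain (time 5–60 min,
temperature 50–150 °C, loading 1–10 mol%, 8 catalysts) draws, per surface,
a per-catalyst amplitude table (N(0, 0.8)), a continuous optimum location
(uniform in the interior, [0.15, 0.85] of each scaled axis) and
per-dimension curvatures (uniform [1, 3]). Task t's latent response is the
blend ρ·shared + (1 − ρ)·privateₜ, mapped through a logistic squash onto
[0, 100]% — yields saturate physically at both ends. ρ = 1 gives identical
chemistry across tasks, ρ = 0 unrelated chemistry, and the grid correlation
between task surfaces increases monotonically with ρ. Observation noise is
additive Gaussian (default sd 2 percentage points) clamped to [0, 100].

Because the blend of concave quadratics is again a concave quadratic per
catalyst, the family's ground-truth optimum is available in closed form;
the grid+refinement search is validated against it.

What the family does *not* emulate: kinetic saturation in time,
temperature–time compensation ridges, heteroscedasticity that grows with
yield, and categorical–continuous interactions beyond an additive offset.
Campaign results on this family therefore demonstrate the machinery and
the transfer effect, not chemistry-specific performance.

`train_table_surrogate` fits the in-repo GP to a user-supplied experiment
table (≥ 20 rows) and exposes the clamped posterior mean as a noiseless
benchmark. A GP rather than a neural network is the default surrogate
form; the emulator architecture is an extension point.

## Study sizes and defaults

Verification studies use dense-oracle problems of N ≤ 8, 20-seed replicate
sets for recovery and transfer-prediction checks, and a 20-repeat,
20-experiment-budget campaign comparison (MTBO with one 96-point auxiliary
table versus STBO with an 8-point LHS) on the default family with ρ = 0.8
and noise sd 2. These sizes are the package's standard desk-scale study
conditions.

## Known limitations

* Exact GP inference is O(N³); campaigns beyond a few hundred observations
  would need approximate inference, which is out of scope.
* Rank-capped ICM (rank ≤ 2) cannot represent arbitrary task covariance
  structure for many tasks.
* Categorical enumeration scales multiplicatively with the number of
  categorical variables; beyond the cap, combinations are subsampled
  rather than searched exhaustively.
* The marginal-likelihood surface is multimodal; multi-restart optimization
  is a heuristic and the recovery studies quantify (not eliminate) its
  failure rate.
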