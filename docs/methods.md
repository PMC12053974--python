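# Methods

## The Paddy field algorithm

`paddyfield` implements the Paddy field algorithm (PFA), a derivative-free
evolutionary optimizer that maximizes an objective `y = f(x)` over an
n-dimensional box without modelling the objective.  Each cycle runs five
phases:

1. **Sowing.** The trial starts from `n_random_seeds` parameter vectors
   drawn uniformly from each dimension's initial grid (`init_range`
   discretized at `init_resolution`).  The grid applies only to this
   initial sow; all later sampling is continuous.
2. **Selection.** The top `threshold` plants by fitness are kept, sorted
   ascending.  *Population* mode selects from every plant ever evaluated
   (exploitative, archive-based); *generational* mode selects only from the
   previous iteration's children (explorative).  When the pool is smaller
   than the threshold — at initiation, or in a thin generation — the
   threshold falls back to `round(0.75 × pool size)`, minimum 1.
3. **Seeding.** Each selected plant receives potential seeds
   `s = s_max (y* − y_t) / (y_max − y_t)`, where `y_t` is the fitness of
   the lowest-ranked selected plant and `y_max` the best.  The best plant
   thus gets `s_max` seeds and the pivot plant none.
4. **Pollination.** Plant density is rewarded: with `ν` the number of
   other selected plants strictly within Euclidean radius `r`, and
   `ν_max` the largest such count in the selection, each plant's seeds are
   scaled by `U = exp(ν/ν_max − 1) ∈ [1/e, 1]`.  The final child count is
   `S = round(U · s)` (half away from zero), with the best plant
   guaranteed at least one child so an iteration cannot go extinct.
5. **Dispersion.** Children are sampled per dimension from
   `Normal(parent value, σ)`, clamped to the limits, rounded for integer
   dimensions.  The default `σ = 0.2`.  In *scaled* mode each child first
   inherits a mutated scaling term `δ_child ~ Normal(δ_parent, 0.2)` and
   uses `σ = (0.2¹⁰)^δ_child`; `δ = 0` gives `σ = 1` (very wide
   exploration — deliberately so, even on unit boxes), `δ = 1` gives
   `σ ≈ 1e-7` (fine refinement).  Lineages whose δ drifts upward become
   local refiners while low-δ lineages keep exploring.

The trial stops when the iteration budget is exhausted or when the
selected plants' fitness range collapses (`|y_max − y_t| ≤ 1e-12`), which
would make the seeding normalization degenerate.

### Adaptive radius

A fixed radius can assign zero neighbors everywhere, collapsing every `U`
to the isolated-plant penalty and starving the population.  When the
user's radius yields all-zero counts, the 0.75 quantile of the pairwise
distance distribution is used instead, lowering the quantile in 0.05 steps
until some plant has a neighbor; if even the 0.05 quantile fails (e.g. a
single selected plant), every plant is assigned exactly one neighbor,
which makes `ν = ν_max` and disables the penalty for that iteration.

### Hyperparameters

| name | meaning | default | notes |
|---|---|---|---|
| `n_random_seeds` | initial sow size | 25 | exhaustiveness of phase 1 |
| `threshold` | plants selected per iteration (integer sense of y_t) | 25 | |
| `s_max` | max seeds for the best plant (a.k.a. Q_max) | 25 | with `threshold`, bounds per-iteration cost |
| `radius` | neighborhood radius r, in parameter units (normalized units when every dimension normalizes) | 0.02 | density scale for pollination |
| `iterations` | propagation cycles after the sow | 10 | |
| `mode` | `population` or `generational` | `generational` | exploit vs explore |
| `gaussian` | `default` (σ = 0.2) or `scaled` (heritable δ) | `default` | |
| `rng_seed` | seed of the single PCG64 stream | 0 | one stream drives sowing, δ inheritance and dispersion |

### Numerical choices

- The closed form of the pollination bonus is taken as
  `U = exp(ν/ν_max − 1)`, the unique single-exponential through the two
  documented endpoints `U(0) = e⁻¹ ≈ 0.368` and `U(ν_max) = e⁰ = 1`.
- `ν_max` is computed within the current selection only, in both modes.
- Neighbor distances use strictly `‖x_j − x_k‖ − r < 0`; exact-boundary
  pairs are not neighbors.  Coordinates are min–max normalized for the
  distance when every dimension has normalization enabled, otherwise raw
  units are used.
- Quantiles for the adaptive radius use the linear-interpolation rule
  over the multiset of ordered pairwise distances.
- All integerization (integer parameters, the 75 % initiation threshold,
  child counts `S`) rounds half away from zero — symmetric and
  locale-independent.  `s` itself stays fractional; only the final `S` is
  integerized.
- Fitness ties in selection break toward the older plant (lower id) so
  runs are deterministic.
- Objectives must return finite values; NaN raises immediately with the
  offending parameter vector in the message.
- Maximization is the native sense; minimize by negating the objective.

### Persistence

A trial checkpoint is one JSON document (population, config, iteration
log, and the exact bit-generator state), written atomically via a
temporary file.  Resuming a mid-trial checkpoint and running k further
iterations is bit-identical to never having stopped, because termination
checks consume no randomness.

## Benchmarks

**Bimodal surface.**  The original two-peak test surface is published
only as a figure, so it is reconstructed here as two isotropic Gaussian
bumps: a broad local peak (amplitude 0.80, width 0.15) at (0.5, 0.5) and
a narrow global peak (amplitude 1.00, width 0.05) at (0.6, 0.1).  The
0.81 success threshold then separates the peaks: only the global peak
region scores above it.  Because the reconstruction cannot match the
original surface's exact difficulty, published success percentages are
treated as ordering context, not value targets.  A caveat worth stating
plainly: at several thousand evaluations, uniform random sampling of the
unit square hits the 0.81 region with near certainty, so *any* optimizer
— this one included — loses a matched-budget success comparison to random
search in two dimensions.  The optimizer's per-evaluation advantage
appears in high-dimensional problems (below), not desk-scale 2-D ones.

**Gramacy & Lee interpolation.**  The target is
`f(x) = sin(10πx)/(2x) + (x−1)⁴` on the inclusive 3001-point grid from
−0.5 to 2.5 (step 0.001); the removable singularity of the first term at
x = 0 is filled by its limit 5π.  The interpolant is the classical
degree-32 trigonometric polynomial
`T(x) = c₀ + Σ a_k cos(kx) + b_k sin(kx)` with 65 coefficients bounded to
[−1, 1].  Unit angular frequency is used because, with this basis,
box-constrained least squares drives the grid MSE to ≈ 0 — consistent
with the near-perfect fits reported for Bayesian optimizers on this task
— whereas period-matched alternatives (e.g. ω = 2π/3) have a constrained
floor near 0.8 and inflate every method's score.  Fitness is the negative
MSE; the benchmark preset is seeds 25, threshold 25, s_max 25, r 0.02, 10
iterations, generational mode, default Gaussian (≈ 1 900 evaluations per
repeat).  The random baseline draws 65 i.i.d. uniform coefficients per
evaluation, 5 000 evaluations per repeat.

**Tversky similarity.**  `S(X,Y) = |X∩Y| / (|X∩Y| + α|X\Y| + β|Y\X|)`
over integer bit sets, defaulting to α = 0.5, β = 0.01 (substructure-
tolerant scoring against a reference fingerprint); α = β = 1 recovers
Tanimoto.  Two empty sets score 0 by convention.

## The discrete planner

The planner drives the PFA over a finite grid of experimental conditions.
Categorical factor levels are embedded as evenly spaced points in [0, 1]
(one axis per factor, table order); each continuous proposal maps to the
nearest *unseen* condition (Euclidean, ties to the lower index), so no
experiment is ever repeated.  After every batch the observed conditions
are re-scored: each metric is min–max normalized over the *seen* rows
only, oriented so 1 is best, and a condition's fitness is the negative
Euclidean distance of its normalized row to the all-ones ideal point.  A
metric constant across seen rows normalizes to 1 (it cannot
discriminate).  Selection is population-mode over the re-scored archive —
the archive must be re-scored wholesale because normalization shifts as
evidence accrues.  If selection degenerates (all selected scores equal),
a fresh random batch of unseen conditions is sown; together with the
guaranteed child of the best plant this ensures a campaign terminates in
at most grid-size experiments.  A campaign's figure of merit is the
1-based position at which the globally best condition (scored on the full
table, used only for evaluation, never inside the campaign) entered the
seen set.

### The synthetic screen

`synth_screen` emulates a full-factorial multi-metric assay screen
(default 6 × 5 × 6 × 2 = 360 conditions, 10 metrics, half maximized and
half minimized — e.g. sensitivities up, background and interference
down).  Each metric follows additive per-factor level effects
(~ N(0, 1)) plus a pairwise interaction between the first two factors
(~ N(0, 0.5)) and measurement noise (~ N(0, 0.5)).  The designated best
condition is the argmax of the ideal-point score of the noise-free
structure, shifted by a margin (default 1.0) in each metric's favorable
direction so it remains the unique optimum under noise.  Placing the best
at the structural optimum mirrors real screens, where the winning
condition combines good factor levels; an arbitrary cell boosted into
first place would be an unstructured needle that no structure-exploiting
planner (or human) could find faster than exhaustion.

What the generator does **not** emulate: correlated metrics beyond the
shared factor structure, heteroscedastic or non-Gaussian readout noise,
plate/batch effects, and any meaningful ordering of categorical levels
(level order — hence the embedding — is arbitrary, so absolute campaign
lengths depend on it; conclusions here are therefore trend-level, e.g.
that smaller `threshold`/`s_max` reach the best condition in fewer
experiments).  Passing tests on this screen show the planner exploits
factor structure under noise; they do not certify performance on any
particular real assay.

## Problem sizes used in tests

Repeat counts were sized for single-CPU runs: 20 repeats for the
interpolation benchmark statistics in the test suite (100 in the
acceptance script), 100 runs for the bimodal success comparison and the
quadratic-recovery check, 100 campaigns plus a 2 × 2 corner scan
(10 repeats per cell) for the planner.  These match the reference
protocol's repeat structure at or near its published scale.

## Known limitations

- Box limits are the only constraint type; no log-scale or categorical
  parameters in the core engine (the planner's embedding covers the
  categorical case).
- Evaluation is sequential; no parallel objective scheduling.
- In generational mode a thin generation can shrink the effective
  threshold; population mode with an oversized threshold relative to the
  sow can select the whole archive every iteration.
- The scaled-Gaussian initial σ = 1 is intentionally wide on normalized
  spaces; on tightly bounded problems most early children clamp to the
  limits.
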