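# Methods

## Modular response analysis as regression

We consider a network of N modules whose activities X = (X₁, …, X_N)
obey dX/dt = f(X, P) for an unknown smooth f and intrinsic parameters
P, and which settles into a steady state after every perturbation.  The
implicit function theorem then defines the exact connectivity
coefficient of module j on module i at the basal steady state,

    rᵉ_ij = −(X_j ∂f_i/∂X_j) / (X_i ∂f_i/∂X_i),   i ≠ j,

with r_ii = −1 by convention.  Experimentally, each node k is perturbed
through one of its own parameters and the relative change of every
node's steady-state level is recorded.  We use the mid-point convention

    ΔX_i/X_i = 2 (X_i(P₀+ΔP) − X_i(P₀)) / (X_i(P₀+ΔP) + X_i(P₀)),

which stays finite down to a full knockout (value −2; −2/3 for a −50%
knockdown).  Collecting these into the global response matrix R
(rows: responding nodes; columns: experiments), first-order expansion
gives, for every experiment k that does not target node i,

    (ΔX_i/X_i)_k = Σ_{j≠i} r_ij (ΔX_j/X_j)_k .

Two solution strategies follow.

**Classical (square) solution.**  With exactly one perturbation per
node, R is N×N and r = −[diag(R⁻¹)]⁻¹ R⁻¹.  The diagonal of this
expression is identically −1; after solving we snap it to −1 exactly to
avoid leaking rounding noise downstream.  We refuse matrices with
condition number above 10⁸ (configurable): the inversion amplifies
measurement noise roughly by the condition number, and surfacing this
is more useful than returning garbage.  The inverse map,
R = r⁻¹ [diag(r⁻¹)]⁻¹ diag(R), generates exact response data from a
known network; the round trip is an identity to ≤ 10⁻⁸ and is used
throughout the tests as an oracle.

**Regression formulation.**  Each row of the linear system above is one
equation of a homogeneous (no-intercept) multilinear regression for the
N−1 unknowns r_i·.  Replicates and extra perturbations simply add rows,
so all data enter one over-determined system per node instead of being
averaged away, and the regression machinery yields residual variances
and confidence intervals.  Experiments targeting node i are excluded
from node i's system because their direct perturbation term is nonzero
and unmodelled.

## Solver family

All fits are homogeneous; the diagonal is never estimated.

* **lse** — ordinary least squares; residual variance RSS/(rows−cols);
  per-coefficient CIs from the t distribution.  A square system returns
  the exact solution with a warning and no CIs.
* **lse_ci** — LSE, then every coefficient whose 95% CI contains 0 is
  set to exactly 0 (no refit; the elimination is a report of
  insignificance, not a model change).
* **tlr** — threshold linear regression: LSE for all N nodes, then a
  single network-wide threshold equal to the 25th percentile
  (linear-interpolation convention) of the pooled estimates; entries
  strictly below the threshold in absolute value are zeroed.  The pool
  is over absolute values by default; a signed pool is available
  (`tlr_pool="signed"`) since the percentile's domain is ambiguous in
  the method's verbal definition.
* **lasso** — L1-penalised fit per node, penalty chosen by
  cross-validation: 50 log-spaced penalties down to 10⁻⁴ of the largest
  useful penalty, 5-fold CV with rows grouped by experiment so
  replicates of one perturbation never straddle a fold, selection by
  minimum mean CV error (not the 1-SE rule).  Exact zeros of the final
  fit count as unselected.
* **step_fo / step_ba / step_bo** — greedy forward, backward and
  alternating subset selection under an information criterion (AIC by
  default, BIC optional).  Moves are evaluated on the Gram matrix, so
  each candidate costs one small dense solve; the final subset is refit
  by LSE for coefficients and CIs.  AIC is deliberately liberal: on
  pure-noise candidates it admits spurious predictors with ~16%
  probability each, which is why the "selects exactly the true
  predictor" property is tested under BIC.
* **mra_bootstrap** — classical solution on replicate means, plus a
  percentile bootstrap (default 100 repetitions) that resamples
  replicate columns with replacement within each experiment; entries
  whose 2.5–97.5 percentile interval spans 0 are zeroed.  Singular
  resamples are discarded and redrawn, with a warning above 20%.

**Prior knowledge.**  A known-null edge set Aᵢ per node removes those
columns from node i's regression, reducing it to N−1−|Aᵢ| unknowns and
increasing the residual degrees of freedom by |Aᵢ|.  The corresponding
output entries are structural zeros.

## Synthetic benchmark generator

Reference networks are drawn directly as sparse signed connectivity
matrices: n_tf regulator columns (each guaranteed at least one
off-diagonal nonzero) and n_ta target-only columns (all off-diagonal
zeros), diagonal −1.  The nonzero budget is ⌊(1−null_fraction)·N(N−1)⌋,
so the null fraction bound (default 85%) holds for every seed, not just
in expectation.  Nonzero magnitudes are uniform on [0.3, 2.0] with fair
random signs — bounded away from zero so that "nonzero" is a
well-defined class for sensitivity/specificity scoring; the upper bound
keeps typical matrices comfortably invertible.  Draws with condition
number ≥ 10⁶ are rejected (≤ 50 retries).

Response matrices are derived analytically via the forward map with the
design-implied diagonal (−2 for KO, −2/3 for −50% KD).  Noise is
additive Gaussian N(0, k·x̄) applied entrywise and independently per
replicate.  The generator works on normalised concentrations (x̄ = 1 by
default) so k is directly the relative noise level.  Two noise modes
exist because adding concentration-scaled noise to a relative-change
matrix is dimensionally loose: `response` (default) perturbs R itself;
`levels` back-computes pseudo-concentrations at scale x̄, perturbs
those, and re-forms the mid-point changes, which keeps noisy entries
inside the valid (−2, 2) range.

What the generator does **not** emulate: dynamics toward steady state,
saturating response nonlinearity (responses are exactly linear in the
coefficients by construction), correlated measurement error, and
degree-distribution structure beyond the TF/TA split.  Tests passing on
these benchmarks therefore demonstrate correct linear-algebraic
recovery and robustness to additive i.i.d. noise — not robustness to
model misspecification; the kinase fixture below covers nonlinearity.

## The kinase-cascade fixture

The ground-truth ODE fixture is a six-stage kinase relay with
MAPK-cascade topology: three tiers (MKKK → MKK → MAPK) of two
activation stages each, Michaelis–Menten activation and deactivation
per stage, and negative feedback from the terminal doubly-active form
onto the cascade input.  Each stage draws on its own conserved pool, so
every speed constant enters exactly one equation; the six perturbable
constants (stage-3 and stage-4 activation, stage-1/2/5/6 deactivation)
form a bijection onto the six nodes, making the standard-MRA
assumption — a perturbed parameter directly affects only its target
node — hold exactly.  Perturbation by fraction q multiplies the
assigned constant by (1+q).

Parameter choices, all fixed at design time and stored in
`src/mrareg/data/mapk6.yaml`:

* Michaelis constants equal to the pool sizes.  With strongly
  saturating (zero-order) kinetics the relay has no stable steady
  state — the feedback loop produces relaxation oscillations — so the
  fixture deliberately operates in the mildly saturating regime.
* Feedback inhibition 1/(1 + X₆/Kᵢ) with Kᵢ = 60 (first-order, n = 1).
* Deactivation Vmax values are solved in closed form so that the basal
  steady state is exactly (30, 36, 96, 108, 114, 120): interior to
  every pool, all Jacobian eigenvalues in the left half-plane, and mean
  level x̄ = 84, which fixes the concentration unit of the fixture and
  hence the absolute noise scale σ = k·x̄ (k = 1% ⇒ σ = 0.84).

Steady states are computed by windowed stiff integration (LSODA,
rtol = atol = 10⁻¹⁰, doubling horizons) until ‖f(X)‖∞ is small, then a
Newton polish of the endpoint brings it below the 10⁻⁹ acceptance
tolerance; the integration establishes which attractor is reached, the
polish removes residual integrator error.  Exact coefficients come from
a central-difference Jacobian (relative step 10⁻⁶; step-halving agrees
to ≤ 10⁻⁴ relative).  Measurement noise N(0, k·x̄) is applied
independently to the basal and perturbed levels of every replicate —
the basal measurement is not exempt — and negative noisy levels are
floored at 10⁻⁹ with a warning before forming mid-point changes.

Documented properties of this fixture (each asserted by a test, none
assumed): classical-MRA error vanishes quadratically as the
perturbation fraction → 0; the noise-free error at −50% perturbation
(0.081) exceeds that at +50% (0.026), the nonlinearity asymmetry; with
k = 1% noise the error at ±1% perturbations exceeds that at ±50% by
orders of magnitude, the noise–intensity trade-off.

## Evaluation

Estimates are discretized to signs ({−1, 0, 1}, or {0, 1} for
existence-only scoring).  The full 3×3 contingency of reference sign ×
predicted sign over the N(N−1) off-diagonal cells is tabulated once;
the six sign-aware counts are derived from it: T⁺/T⁻/T⁰ are the
diagonal cells, F⁺ is "predicted +1, reference ≠ +1" and F⁻/F⁰ by the
same pattern, so the six counts partition the off-diagonal cells
exactly.  Se = (T⁺+T⁻)/P with P the nonzero reference edges;
Sp = T⁰/N with N the zero reference edges; either is undefined (None)
when its denominator is empty.  Additional metrics: exact squared error
Σ(rᵉ_ij − r_ij)²; AUROC over |coefficient| scores (trapezoid over the
threshold sweep, equal to the mid-rank Mann–Whitney statistic — for
selector methods the pre-selection magnitudes are the natural scores);
the top-x% magnitude filter (threshold = smallest of the top
⌈x%·N(N−1)⌉ magnitudes, strict-below zeroing so threshold ties
survive); and the signed distance (se+sp−1)/√2 of the operating point
to the chance diagonal.

## Problem sizes and defaults used in the shipped studies

The package's own validation studies run at desk scale: benchmark
comparisons at N = 100 with 5 seeds and 3 replicates, noise k = 10%,
KO designs; replicate-benefit and CI studies on the 6-node fixture with
20 noise draws; sparsity and round-trip properties over 20–50 seeds and
N up to 300.  These sizes were chosen so the full study suite completes
in minutes while every comparison retains a comfortable effect size
(e.g. the classical-vs-TLR error gap at N = 100 is three orders of
magnitude).  Larger grids — the full (30…1000)-node ladder — are
reachable through `make_benchmark_suite`/`run_sweep` with the same
code paths.

## Known limitations

* The classical path requires a square design; mixed KO+KD designs are
  handled only by the regression path (per-node systems simply gain
  rows).
* Mean-squared-error monotonicity in noise holds robustly for the
  replicated least-squares fit but **not** for the classical inverse,
  whose error distribution is heavy-tailed near ill-conditioning; a
  single seed can dominate the mean.  Comparisons against classical MRA
  should use many seeds or robust summaries.
* LASSO needs genuine row redundancy (replicates or extra
  perturbations); on a square system cross-validation folds are
  experiment-poor and the penalty choice degenerates.
* The fixture's stages own separate conserved pools; it does not model
  shared-pool double phosphorylation, processivity or enzyme
  sequestration.
* Module aggregation (which molecules form a node) and time-course
  fitting are out of scope.
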