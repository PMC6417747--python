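# Methods

This note documents the models, numerical choices and validation logic of
`rewardscape`, in the spirit of the methods documentation of simulation
packages: what is computed, under which assumptions, and what the tests do
and do not establish.

## Reinforcement landscapes

A landscape is a piecewise-linear map from normalized reach angle θ
(z-score relative to a participant's baseline mean and SD) to reward
probability, stored as affine segments with explicit interval-endpoint
ownership; probability is zero outside the stored segments.

Single-slope landscapes (the steep/shallow experiment) have maximal success
rate m (steep m = 1, shallow m = 2/3), a rising line
(m/3 − 1/9)·θ + 1/3 from its zero crossing at −3/(3m − 1) up to θ = 3, and
a plateau at m on 3 < θ ≤ 6. The intercept 1/3 at θ = 0 means baseline
behaviour is rewarded on one third of reaches; the slopes are 2/9 and 1/9
per z-score. Counterclockwise variants are exact mirrors about θ = 0.
Valley landscapes (the two-slope experiment) put the same two slopes
back-to-back: with the steep side clockwise, 2/3 on [−6, −3), −θ/9 + 1/3 on
[−3, 0), 2θ/9 + 1/3 on [0, 3], 1 on (3, 6].

The lower support bound −3/(3m − 1) is the unique value consistent with the
printed slope, the 1/3 intercept, and continuity (steep crossing −1.5,
shallow −3.0). Endpoint ownership follows the defining inequalities; at
interior breakpoints the function is continuous so ownership is
observationally irrelevant, and the only true discontinuities are the drops
to zero at the outer support edges.

Pooling convention: series from landscapes rising counterclockwise are
multiplied by −1 so that "toward the (steep) slope" is always positive;
rewards and phases are untouched. Landscapes live on the z-score axis only;
conversion to native degrees goes through `BaselineStats`.

## The learner

Three parameters: update proportion α ∈ [0, 1], motor SD σm > 0,
exploration SD σe ≥ 0. Defaults (0.40, 0.81, 0.90) are the best-fit values
for the behavioural experiments; σm is a little below 1 because baseline
z-scoring normalizes single-trial variability that includes no exploration
component.

Design choices where the trial loop is underdetermined by the update
equations alone:

* **No-feedback trials** (baseline and washout) neither update the aim nor
  add exploration variance: absence of feedback is not a failure signal,
  and retention through washout requires the cached aim to persist. The
  first feedback trial therefore runs at variance σm².
* **Initial aim** is 0 z (the baseline mean, by the normalization that
  defines the axis).
* **Exploration gating is binary** on the previous outcome, exactly as in
  the update rule; a graded alternative (variance scaling with 1 − R(θ) of
  the previous reach) was checked and changes cohort learning curves only
  marginally.
* **2D variant**: isotropic noise (same σm, σe per axis, independent
  draws), the same scalar α applied componentwise, reward iff the endpoint
  lies in the rectangle. The noise covariance is not constrained by the 1D
  model; isotropy is the minimal assumption.

Cohorts use a master `SeedSequence` that spawns one independent substream
per individual; each individual's normal and uniform streams are pre-drawn
so that the trial loop is vectorized across individuals while remaining
bit-reproducible and chunk-size-invariant (up to float summation order in
the mean). 10,000 individuals × 450 trials simulate in about a second.

## Expected reward and the optimal intended aim

Expected reward for an intended aim integrates the Normal reach density
against the landscape; reach variance combines motor noise with
reward-gated exploration, σ² = σm² + (1 − p) σe². Where p is evaluated is a
genuine modelling fork, so all three readings are implemented
(`variance_at`):

* `"mean_success"` (default): p is the session-average success probability
  the learner attains on that landscape, so σ is a constant per landscape
  and the integral is a true convolution. The average can be passed
  explicitly or estimated self-consistently by simulating the model
  (default n = 2000 individuals, seeded); the model yields p̄ ≈ 0.87 on the
  steep landscape and ≈ 0.56 on the shallow one, giving optima of 3.96 and
  3.79 z. This convention reproduces the optima quoted for the behavioural
  experiments and is the package default.
* `"theta"`: p = R(θ) at the integrand point. This is the literal pointwise
  reading; the kernel is then not a normalized density (no renormalization
  is applied), the integral can slightly exceed the landscape maximum near
  a plateau, and the optima come out lower (3.84 / 3.78).
* `"aim"`: p = R(aim), a convolution whose width varies with the aim
  (optima 4.01 / 3.83).

Quadrature is trapezoidal on a default grid of [−10, 10] z at 0.005
spacing (the grid must cover the landscape support with a 4σ margin); the
grid argmax is refined by bounded scalar search to below the grid
resolution, ties breaking toward the smallest |aim|, and maxima tied beyond
tolerance are reported as errors. Halving the spacing moves the optimum by
less than 0.01 z. The integrals are validated against Monte-Carlo oracles:
direct sampling for the constant-σ convention and importance sampling for
the position-dependent kernel, both at 10⁶ draws within three standard
errors.

## Learning-curve statistics

The mean experimental curve is fit by θ_i = a (1 − e^{−i/λ}) with i = 1 on
the first feedback trial, so λ is in units of feedback trials. Fitting is
nonlinear least squares with a multi-start over λ ∈ {5, 20, 50, 100, 200}
(lowest residual sum of squares wins); curves with asymptote
indistinguishable from zero are flagged as unidentifiable rather than
assigned a meaningless λ. Simulated cohorts at the default parameters give
λ ≈ 32 (steep) and ≈ 54 (shallow); the published values for this model
family (28.0 and 49.6) correspond to an update proportion a few hundredths
above the rounded α = 0.40 used here, which the package deliberately keeps
at its quoted value.

Bootstrap inference resamples participants (not trials) with replacement,
10,000 resamples by default, refitting each resample's mean curve
(warm-started from the point fit, multi-start fallback, failures dropped
and counted). The one-tailed p for λ_a < λ_b is the mass of the
λ_b − λ_a resample distribution at or below zero. Participant-level
resampling is the standard choice for between-subject inference; the
two-group difference distribution is exactly symmetric for identical
groups, which the tests exploit.

Classification uses the mean of the last 100 feedback trials: learners at
≥ 1.0 z on single-slope landscapes; clockwise / center / counterclockwise
at ±1.0 z on valley landscapes (robustness cutoffs ±0.5 and ±1.5
supported). N-th-success prediction conditions on the slope (sign of θ,
after pooling) of an individual's N-th success overall — successes at
exactly θ = 0 belong to neither slope — and reports conditional final-class
frequencies with explicit undefined (NaN) entries for empty conditioning
sets. Variability-by-history bins the trial-to-trial change Δθ by the
previous outcome (optionally the previous two), plus late-baseline (session
trials 25–50) and washout bins; for an α = 0 learner the closed forms
√2·σm (after success) and √2·√(σm² + σe²) (after failure) hold and anchor
the tests. Contingency tables use the exact two-sided hypergeometric test,
cross-checked against a brute-force enumeration oracle.

## Calibration

`fit_parameters` minimizes the summed squared error between simulated and
target mean experimental curves, jointly over the steep and shallow
conditions (both conditions constrain the fit; neither alone identifies all
three parameters well). The objective is stochastic, so every evaluation
reuses the same per-condition seeds (common random numbers); at
n_sim = 2000 repeated evaluations at a point are identical by construction
and the surface is smooth enough for a coarse 4×4×4 grid pass followed by
Nelder-Mead with an out-of-bounds penalty. Parameter recovery from
synthetic targets generated at (0.40, 0.81, 0.90) lands within about ±0.02
of each true value (tolerance asserted: ±0.1). Bootstrap spread is
available by refitting on participant-resampled targets. Difference-based
initial guesses for the noise SDs follow the closed forms above; they are
also exposed directly as `initial_guess_sigmas`.

## Scenarios

The replication scenarios run the identical learner in other geometries,
in native units (degrees or mm), with configurable schedules whose defaults
are representative rather than bit-faithful to the original studies —
their published schedules are not fully specified, so the scenario
checks are properties, not numbers:

* **Gradual rotation**: reward iff the reach falls in a window (default
  3°) whose centre steps 1° every 40 trials up to 8°. The cohort mean
  tracks the ramp approximately linearly; a window much wider than the
  noise removes tracking.
* **Shifted cursor**: the cursor is displaced each trial by a skew-normal
  draw (default scale 10 mm, shape 4); reward iff the shifted cursor is
  within the 20 mm target. Learners compensate toward, but systematically
  short of, the hit-maximizing position — greedy suboptimality. A
  symmetric shift yields an asymptote at its centre of symmetry.
* **2D rectangle**: with a long/thin target (default 1.5 × 30), lag-1
  autocorrelation of endpoints is strongly positive along the
  task-irrelevant axis and near zero along the task-relevant axis —
  random-walk drift emerges from reinforcement feedback alone. A square
  target makes the axes exchangeable.
* **Noise sweep**: λ decreases monotonically in both σm and σe on both
  gradients (the sweep treats the noise values as abstract magnitudes).
* **Baseline-reward sweep**: shifting the shallow landscape's intercept
  (slope fixed) changes λ only marginally relative to the steep/shallow
  gap, while lowering it delays the first success (geometric waiting
  time).

## What the synthetic data do and do not show

The simulator is also the package's data generator: cohort fixtures emulate
the 450-trial protocol (explicit NA rewards on no-feedback trials, JSON
sidecar with parameters and seed). Synthetic cohorts reproduce the
structure of the behavioural dataset — schedule, normalization, outcome
coding — but contain none of its idiosyncrasies: no participant
heterogeneity in (α, σm, σe), no drift, fatigue, lapses or explicit
strategies, and baseline z-scoring is exact rather than estimated from 25
trials. Analyses validated on synthetic cohorts are therefore validated as
*procedures*; quantitative agreement with human data (bootstrap p-values,
learner counts, R² against behavioural curves) requires the recorded
dataset, which the package reads through the same trial-table format but
does not ship.

## Problem sizes and tolerances

Default sizes were chosen so every check converges well inside its
Monte-Carlo noise: 10,000-individual cohorts for time constants (λ spread
across seeds ≈ ±0.3), 2000 for valley-classification frequencies and
success-rate estimates, 10⁶ draws for quadrature oracles (3 SE bands),
10⁴ trials for closed-form variability checks, 40 replicate 40+40 cohort
pairs for the gradient-speed ordering, and n_sim = 2000 with 20,000-
individual targets for parameter recovery. Stochastic assertions use fixed
seeds chosen a priori, so the suite is deterministic.

## Known limitations

* The learner has no error-based component, no use-dependent or savings
  effects, and no reaction/movement-time model; it is a model of
  reinforcement-driven aim adaptation only.
* With zero gradient within reach of the movement noise the model cannot
  adapt; it is a model of local learning over small regions of the
  workspace.
* The position-dependent expected-reward kernel (`variance_at="theta"`) is
  intentionally unnormalized (the literal reading); treat its absolute
  values with care near plateaus.
* Holm-Bonferroni family-wise correction across arbitrary test sets is out
  of scope; p-values are reported per test.
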