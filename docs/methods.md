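# Methods

## Problem

Wrist-worn ActiGraph-style accelerometers summarize movement as integer
"activity counts" per epoch (here 5-s epochs, axis 1 being the primary
analysis signal).  Distinguishing seated sedentary behavior from
light-intensity walking in 5–11-year-old children requires (a) knowing how
much dominant vs non-dominant wrist placement changes the count
distribution during seated manual tasks, and (b) a count threshold
("cut-point") below which an epoch is classified sedentary.  The raw cohort
data behind the published calibration are not deposited, so this package
couples the analysis pipeline to a synthetic-cohort generator calibrated to
the published per-activity count quantiles.  Passing tests therefore show
that the *pipeline* recovers the quantities the generator is calibrated to,
not that the published empirical values are reproduced from raw data.

## Synthetic cohort model

Each activity × wrist marginal of axis-1 counts is a zero-inflated
lognormal (ZILN): probability mass `pi` at zero and a LogNormal(`mu`,
`sigma`) positive part, so the quantile function is

    Q(tau) = 0                                         for tau <= pi
    Q(tau) = exp(mu + sigma * z((tau - pi)/(1 - pi)))   otherwise,

with `z` the standard normal quantile.  The family was chosen because the
published descriptives (median and IQR per activity × wrist) are zero-heavy
and strongly right-skewed; any three-parameter family matching three
quantiles would do, and ZILN is the documented default.

`fit_ziln` inverts (q25, q50, q75) to (pi, mu, sigma):

- all three positive: `pi` is bisected in [0, 0.25) with (mu, sigma) in
  closed form from q50/q75 at each candidate; the triple is representable
  iff `q50^2 >= q25*q75` (at pi = 0 the lognormal's log-symmetry pins
  Q(0.25) at `q50^2/q75`), otherwise a validation error is raised.  All
  reference rows are representable.
- q25 = 0 < q50: pi = 0.25, (mu, sigma) in closed form.
- q50 = 0 < q75: pi = 0.50 and mu = log(q75) (the 75th percentile falls at
  the positive part's median, so sigma is under-identified); sigma is taken
  from the dominant-wrist fit for the same activity, or 1.0.
- all zero: pi = 0.75, mu = 0, sigma = 0.5 (explicit convention for the
  near-motionless TV row).

Cohort structure, per child `i` and epoch `t`:

- a per-child multiplicative effect `exp(e_i)`, `e_i ~ N(0, s^2)` with
  `s = child_effect_sd = 0.3` by default, shared across activities and
  wrists (an "active child" is active everywhere).  The within-child
  log-SD is shrunk to `sqrt(sigma^2 - s^2)` so the *population* marginal is
  exactly the fitted ZILN after integrating over children — population
  quantiles stay at their targets regardless of `s`.  The published tables
  report no between-child dispersion, so `s` is a config knob; 0.3 (a ±35%
  one-SD child effect) is a realistic default for count data of this kind.
- wrists are coupled epoch-by-epoch by a Gaussian copula with correlation
  `rho` (0.95 for walking, where both arms swing together; 0.5 for seated
  activities, where hands move far more independently), preserving both
  marginals exactly.
- axes 2 and 3 are the axis-1 draw scaled by 0.7 / 0.6 with lognormal
  noise (0.2 log units).  No published axis-2/3 descriptives exist; these
  are synthetic conventions, flagged as such.
- positive draws are rounded to the nearest integer after the child effect
  (device exports are integer counts).
- with probability `p_stand` (default 0.05) a child's seated session is
  contaminated: a contiguous run of 20–60% of its epochs is replaced on
  both wrists by walking-distributed counts and the observation log marks
  that child × activity `seated_verified = False`.  The downstream
  direct-observation filter must remove exactly these sessions.

What the generator does **not** emulate: raw 30–100 Hz accelerations,
autocorrelation of counts within a session beyond the shared child effect,
age/sex effects, device non-wear, and the real protocol's unbalanced
activity participation (every synthetic child performs every activity; the
observation filter then creates realistic missingness).

### Empirical quantiles at the zero atom

For targets with q25 = 0 (or q50 = 0) the fitted distribution places an
atom of exactly `pi` at zero.  The plug-in sample quantile does not
converge at an atom boundary — it oscillates between 0 and the smallest
positive values with the binomial fluctuation of the zero count — so
round-trip tests check zero targets through the zero *fraction*
(`P(X = 0) >= tau` within binomial sampling error), which is the statement
that actually characterizes `Q(tau) = 0`.  Positive targets are checked as
plain relative errors.

## Quantile contrasts

The wrist contrast at level tau is the coefficient of a wrist indicator in
a tau-quantile regression.  With one binary covariate the design is
saturated, so the coefficient equals the difference of the two per-wrist
sample quantiles; that closed form is the implementation, and statsmodels'
`QuantReg` is kept as an independent cross-check in the test suite.
Sample quantiles use linear interpolation between order statistics
(position `(n - 1) * tau`; the common "type 7" scheme).  Statistical
software differs in quantile conventions, but the differences vanish at
these sample sizes (thousands of epochs per cell).

95% CIs come from a percentile bootstrap with B = 100 replicates that
resamples *children* with replacement — a child drawn k times contributes k
copies of its full epoch block on both wrists — respecting the nesting of
epochs within children.  B = 100 is too small for BCa, hence the percentile
interval; B is configurable.  A contrast is flagged non-converged when the
replicate distribution is degenerate (all replicates identical) or both
wrists' observed tau-quantiles sit in the zero atom, mirroring the dashes
printed for the low-count cells; significance means the 95% CI excludes 0
(the published table bolds p <= 0.05 without naming a test; CI exclusion is
the reproducible reading).

Simulation coverage: on cohorts of 150 children the nominal-95% clustered
percentile CI for the median contrast covered the true value in 97.5% of
200 replicates (the test suite asserts >= 90%).  The single-cohort median
contrast is unbiased but carries a sampling SD near 3 counts/5 s under
those conditions, dominated by epoch-level noise; recovery checks therefore
average the estimator over four independent cohorts of the same size.

## Cut-point derivation

The ROC contrasts the light class (walking epochs; walking is the positive
class, which makes sensitivity and specificity come out nearly symmetric)
against the single seated activity with the highest counts on the wrist and
signal under analysis (ties: higher 75th percentile, then lexicographic) —
a threshold separating the most active seated behavior from walking
necessarily classifies quieter seated behaviors as sedentary.  A pooled
all-seated mode exists but is off by default.

`youden_cutpoint` scans all distinct observed values plus one past the
maximum and returns the smallest threshold maximizing sensitivity +
specificity, under the rule `count >= threshold -> light`.  AUC is the
rank (Mann–Whitney) statistic: the probability a random light epoch
outranks a random sedentary epoch, ties counted half, identical to the
trapezoidal area under the empirical ROC curve.

`calibrate` first splits children once (seeded, child-level) into
calibration and validation sets (fraction 100/167 by default), then
partitions the calibration children into k = 10 folds.  Each iteration
derives the threshold on the other folds and — by default — evaluates
sensitivity, specificity and AUC on the held-out fold ("out-of-fold"); an
in-fold evaluation mode exists because either reading of the original
procedure is defensible.  Thresholds and metrics are averaged over
iterations (thresholds reported raw and rounded to the nearest integer).
The "10-fold" language could also mean ten independent repeats; that
reading is available as `mode="repeats"` (Monte Carlo hold-outs of 1/k of
the calibration children).  Validation AUC is computed on the untouched
validation children with a child-level bootstrap CI (B = 200, chosen for
implementation simplicity over a DeLong interval); the calibration AUC CI
is the normal approximation over fold values (mean ± 1.96·SD/√k).  All
splits are at the child level, never the epoch level, so no child's epochs
appear on both sides of any split.

## Sedentary-minutes summary

Epochs below the cut-point are sedentary, at or above it light-or-above —
the same boundary convention as the threshold search.  Minutes are
`n_epochs * 5 / 60`; sedentary plus light-or-above minutes equal total
minutes exactly because every epoch is classified.  No bout-length, breaks,
or non-wear logic is applied.  The packaged published cut-points (axis 1:
203 non-dominant / 229 dominant; axis 2: 200/220; axis 3: 201/219; VM:
397/428 counts/5 s) can be applied directly.

## Pipeline and problem sizes

`run_pipeline` chains simulate → filter → compare-quantiles → calibrate →
classify, writes TSV outputs shaped like the published descriptive and
cut-point tables, and a manifest with SHA-256 digests; identical configs
reproduce byte-identical outputs.  Defaults follow the study conditions:
167 children, 60 five-second epochs (5 min) per activity, nine activities,
B = 100 bootstrap replicates, k = 10 folds, calibration fraction 100/167.
Parameter-recovery checks use 150-child cohorts, and the bootstrap-coverage
check uses 200 simulation replicates at n = 150 children — sizes at which
the estimators' sampling error sits comfortably inside the stated
tolerances while a full run stays interactive.

## Numerical choices and edge cases

- ZILN bisection: 80 halvings of [0, 0.25) (final interval < 1e-24), fit
  verified to relative 1e-6 at all positive targets.
- Degenerate triples (q25 = q50 = q75 > 0) yield sigma = 0, a point mass.
- Empty quantile inputs, missing wrists/activities, non-positive
  cut-points, fewer than 2 children in the bootstrap, and a calibration in
  which every fold lost a class all raise validation errors (a single fold
  missing a class is skipped with a warning).
- Epoch re-integration drops a trailing remainder with a warning; totals
  are otherwise conserved.
- Vector magnitude is computed from epoch-summed axis counts and kept
  real-valued; device firmware computing VM per raw sample would differ.
- `p_stand` may be 1.0: every seated session is then flagged, the filter
  leaves only walking, and calibration aborts for want of a seated class —
  the expected failure mode, surfaced with the stage name.

## Known limitations

- The generator matches three quantiles per marginal; the full shape of the
  real count distributions (and hence absolute AUC/sensitivity levels) is
  not identified by the published tables, so ROC *levels* on synthetic data
  are plausibility surfaces, while orderings (dominant cut-point above
  non-dominant, non-dominant AUC above dominant) are reproduced.
- Bootstrap CIs with B = 100 are approximate.
- The published 317 vs 337 sedentary minutes over an 8-h camp day depend on
  unavailable free-living data; only the direction of the contrast (a lower
  cut-point yields no more sedentary minutes on identical series) is
  checked.
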