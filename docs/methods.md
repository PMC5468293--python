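# Methods

This note documents the models, conventions and numerical choices behind
`gaitsig`, and what the synthetic-data tests do and do not establish about
real recordings.

## Stride kinematics

A stride is delimited by consecutive swing onsets of the *same* paw; stride
length is the distance between the corresponding consecutive touchdown
positions along the runway axis.  With this convention the identities

```
stride duration = swing duration + stance duration
stride velocity = stride length / stride duration
cadence         = 1 / stride duration
swing speed     = stride length / swing duration
```

hold exactly by construction, and the package asserts them to 1e-9
relative on every derived record.  Times are accepted as real seconds;
when frame numbers are supplied they are divided by the frame rate, and
the tolerance for identity checks after quantization is one frame period
(1/120 s at the typical 120 frames/s).  Cadence is per stride
(strides/s); a documented factor of 120 converts to steps/min for biped
reporting.  Left/right hindlimb pooling is an explicit call
(`select_paws`), never silent — asymmetric lesion models make silent
pooling dangerous.

Trial filters mirror standard runway practice: strides from touch-cued
trials are removed (tactile prompting produces erratic measures), trials
with fewer than 3 strides are dropped, at most 4 trials per subject and
condition are kept, and the first and last stride of each pass can be
excluded as starting/stopping steps.  The filter report always states the
cue composition and the counts removed per rule.

Base width is computed as the absolute lateral distance between a
touchdown and the nearest-in-time contralateral touchdown.  Whether
touchdown or mid-stance positions are the better anchor is genuinely open;
touchdowns were chosen because they are the positions the event schema
already carries.  Base width is optional and never modelled.

Human walkway records arrive as trial averages (gait speed, stride
duration, swing duration); stride length is speed x stride duration,
stance the remainder, with a natural-log stance variant for log-scale
modelling.  Human data are visualized only — per-subject clustering and
covariates (age, height, sex) would demand mixed or multilevel models that
are deliberately out of scope.

## Velocity-dependence models

Three families are fit to each parameter over a closed velocity interval,
default [3, 16] cm/s (the walking range; mouse walking averages about
9 cm/s with SD 6 cm/s, and both boundary values are retained):

* linear, 2 parameters;
* one-phase exponential association `Y0 + (Plateau − Y0)(1 − e^(−Kv))`,
  3 parameters, `K > 0`;
* two-phase association with two spans and rate constants,
  5 parameters, `KFast > KSlow > 0`.

These are the standard parameterizations used by commercial curve-fitting
software, so estimates are directly comparable with that software's
output.  `range_scan` reproduces the range-selection exercise —
systematically omitting slow bins from 0 up and fast bins from 25 down —
and reports preferred family, SS and diagnostics per range without
deciding a "best" range itself.

**Fitting.**  The exponential families are linear in everything except
their rate constants, so fits use variable projection: the optimizer
searches over log rate constants only (bounds 1e-6 to 100 per cm/s) while
the linear parameters are profiled out by exact least squares at every
step.  Multi-start (10 starts; K log-spaced over [0.05, 2], two-phase
slow-K starts paired with fast/slow ratios of 8 and 40) guards against
local minima, with ties broken toward the lowest rate constant.
Convergence tolerances are 1e-12 on the scaled step and gradient.  This
makes ~10 ms one-phase fits whose SS is reliably the global minimum — a
property the shared-curve F-test depends on, since a separate fit that
stalls above the pooled SS would produce a negative extra sum of squares.
Standard errors come from the Gauss–Newton covariance
`s² (JᵀJ)⁻¹` with the analytic Jacobian of the full parameter vector;
confidence bands use the delta method with a t quantile on the residual
df.  Stance duration can be fit on the identity or natural-log response
scale; identity is the default.

**Model selection.**  Candidates ordered by parameter count (2, 3, 5) are
compared sequentially with the extra sum-of-squares F-test; the complex
model must earn its parameters at p <= 0.05.  Linear is not a strict
submodel of the one-phase family; the families are treated as quasi-nested
through their df differences, exactly as the commercial software does, and
F is clipped at 0 (p = 1) when the complex model happens to fit worse.  A
simpler fit whose SS is below 1e-12 of the response total sum of squares
is treated as perfect and ends the chain, avoiding a 0/0 ratio on
noise-free data.

**Diagnostics.**  Residuals ordered by velocity feed a Wald–Wolfowitz runs
test and the D'Agostino–Pearson omnibus K².  The runs test uses the exact
conditional distribution of the run count given the sign counts (computed
with log-gamma binomials, stable at any n) and reports a two-sided p:
`2·min(P(R ≤ r), P(R ≥ r))` capped at 1.  An all-one-sign residual vector
has a degenerate conditional distribution; operationally it means the
curve sits entirely above or below the data, so it is reported as p = 0
with a `degenerate` note.  The normality test is refused below 8
residuals.

## Shared-curve comparison

`compare_two` fits the chosen family to A, B and the pooled data and forms

```
F = ((SScomb − (SSA+SSB)) / (DFcomb − (DFA+DFB))) / ((SSA+SSB)/(DFA+DFB))
```

with p from the F distribution on (numerator, denominator) df; p < alpha
(default 0.05, conservative option 0.001; no family-wise adjustment by
default in `compare_groups`) means the datasets need separate curves.  The
numerator df always equals the family's parameter count.  The same family
and range are imposed on both groups and the pool; the family should be
selected on baseline data first.  Whether to re-select the family after an
intervention is genuinely open; family reuse is the default here because
the question being asked is whether the *baseline* signature still holds.

When curves are not shared, `shift_summary` reports per-parameter
differences (B − A) with Wald 95% intervals from the two fit covariances —
documented as approximate.  For linear fits `classify_shift` labels the
change as intercept-shift, slope-shift or both according to which
difference CIs exclude zero; for nonlinear families raw parameter
differences are reported without a bespoke horizontal-shift statistic.
Perfect separate fits (combined SS of the separate fits below 1e-12 of the
pooled total SS) yield F = inf, p = 0 and a `degenerate` flag rather than
an exception, since tiny exactly-collinear tables hit this case.

## Conventional analyses

Normality gates use D'Agostino–Pearson at p < 0.05 and are refused (rank
route, flagged) below n = 8.  Two-sample comparisons route to pooled
t-tests or Mann–Whitney (Wilcoxon signed-rank for paired data); three or
more groups route to one-way ANOVA with Holm–Šídák pairwise comparisons on
the pooled within-group variance, or Kruskal–Wallis with Dunn's rank-sum z
comparisons under a Šídák-style family correction at family-wise 0.05.
All routing decisions are part of the report.

The paired-t sample-size calculation iterates the exact noncentral-t power
to the smallest n meeting the target.  Printed pre/post summaries do not
determine the SD of the paired differences, so the effect-size convention
is an explicit argument: mean difference divided by the pooled SD of the
two summaries (default), by the pre or post SD, or by the
independent-samples difference SD.  For the open-field distances
21.4 ± 7.2 m to 11.6 ± 6.5 m at alpha 0.05 and power 0.95 these give
n = 9, 10, 8 and 15 respectively.

## Synthetic data: what it emulates and what it does not

Velocities are truncated-normal (mean 9, SD 6, truncated to [3, 16] cm/s).
Stride length and swing duration are generative — curve(v) plus
independent homoscedastic Gaussian noise — and all other parameters are
derived so the stride identities hold exactly.  Default curves (one-phase
30→80 mm with K 0.15 for stride length; gently declining linear swing
duration, 0.18 s minus 0.004 s per cm/s) are plausible shapes for mouse
walking with noise SDs of 3 mm and 0.01 s; they are package defaults, not
estimates from any cohort.  Cohort structure is 10 subjects x 4 trials x
10 strides = 400 strides.

The generator intentionally omits several features of real data:
per-animal random effects (every stride is exchangeable within a cohort),
heteroscedastic or non-Gaussian noise, correlated noise across parameters
of one stride, cueing structure, and pathological patterns such as
circling or freezing.  Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated
assumptions — not that real cohorts satisfy those assumptions.  In
particular the null calibration of the shared-curve test (empirical
rejection 0.056 at nominal 0.05 over 500 replicate pairs) would not
survive strong per-animal clustering; a mixed-model extension would be
required there.

Two illustrative constructions are provided.  The *velocity split*
assigns a random quarter of a cohort to a faster and a random quarter to a
slower group and rank-splits the remaining half by velocity — two groups
with different speeds but identical gait quality.  The *offset
construction* adds 5 mm to the stride length of one random half, with
velocity held fixed (the shift is applied to the parameter as plotted
against the original velocities; a flag re-derives velocity instead).
Because the curve family is established on baseline data before any
comparison, the split construction is compared under the selected
(typically one-phase) family; imposing a linear form there would confound
curvature lack-of-fit with the velocity difference between the groups.
The offset construction is compared under the linear form, whose intercept
difference is the natural estimate of the injected shift; both halves
share the same velocity distribution, so any curvature misfit cancels
between groups.  Signature-shift injections are affine
(`y → delta + scale·y`) with presets for a bilateral-loss-like phenotype
(downward stride-length intercept, shorter swing, higher cadence) and a
unilateral-lesion-like phenotype (stride-length slope reduced with the
intercept preserved by pivoting about v = 0).

## Problem sizes

Replicate studies use 200 replicates for the construction and
model-preference rates and 500 replicate pairs (n = 200 strides per group)
for the null calibration; parameter recovery uses n = 400 (n = 1000 for
the weakly identified five-parameter two-phase family).  These sizes give
Monte-Carlo standard errors of about 1.5–2 percentage points on the
reported rates.

## Known limitations

* No mixed/multilevel models: comparisons are valid within a cohort or
  between tightly matched cohorts, not across arbitrary groups.
* Wald shift CIs and the quasi-nested F chain are approximations; the
  two-phase family is weakly identified at walking-range sample sizes.
* The runs-test p for the all-one-sign case is an operational convention,
  not a probability statement.
* Human data support derivation and visualization only.
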