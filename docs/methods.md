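# Methods

## Calibration model

An AD5933-class impedance analyzer reports, per sweep frequency, a pair
of dimensionless readouts (Rr, Ir) whose magnitude and angle are related
to the true impedance through an unknown frequency-dependent instrument
gain and phase. Single-point calibration against a known resistor R_cal
removes both:

- gain factor `FG(f) = (1/R_cal) / |raw_cal(f)|`,
- system phase `phase_Z(f) = atan2(Ir_cal, Rr_cal)`,

after which `|Z| = 1/(FG·|raw|)` and `phase_C = atan2(Ir,Rr) − phase_Z`,
wrapped to (−π, π]. The gain-factor convention is the unique reading
under which applying the calibration to its own readings returns exactly
R_cal with zero phase — the self-calibration identity, asserted in
tests. The arctangent is always the four-quadrant form; a single-argument
arctangent would lose quadrant information for reactive loads. The
default sweep (start 10 kHz, step 280 Hz, 255 steps, R_cal = 470 Ω,
2 Vpp) mirrors the screening device's configuration; frequencies are
exact integer-hertz arithmetic, so the four working frequencies fall on
sweep indices 0, 80, 160 and 240. Calibration against a complex
(reactive) reference is out of scope — the device calibrates on a pure
resistor, and the series-RC phantom (100 Ω + 100 nF) appears only as a
closed-form verification target.

## Feature set and screening

Each measurement contributes 4 frequencies × (magnitude, phase, real,
imaginary) + (age [years], weight [kg], sex [0 = female, 1 = male],
height [cm]) = 20 attributes, in a fixed documented order. Attributes
are z-scored (parameters learned on training data only) before any
distance or classifier computation: Euclidean distance across raw
ohm/year/kg scales would be dominated by the largest-scaled attribute.

Chi-square screening tests each attribute's independence from the label
on a contingency table. Continuous attributes are quantile-binned
(default 4 bins); attributes with at most `n_bins` distinct values are
used as categories directly (quantile edges collapse on discrete data);
constant attributes are reported as p = 1. The Hosmer–Lemeshow statistic
uses the conventional 10 decile-of-risk groups and a chi-square
reference with g − 2 degrees of freedom. Both group counts are
configurable; the discretization scheme is this package's documented
choice, since only the tests themselves — not their construction — are
fixed by the screening protocol.

## Classifier

Binary logistic regression, P = 1/(1+e^{−h}) with h = w·x_std + b,
fitted by L-BFGS with L2 regularization at C = 1 (the solver family that
performed best for this problem; the tag is stored with the model).
Decision threshold 0.5 unless configured. Prediction is computed
directly from the stored weights rather than through the fitting
library, so the JSON persistence and the C-header export (`float32`
constants `W, B, MU, SIGMA`) round-trip to ~1e−5 in probability — the
header is what a microcontroller deployment compiles in.

## ATSS — active training by seed selection

Per-sample silhouette widths on standardized features:
a_i = mean Euclidean distance to same-class samples (self excluded),
b_i = mean distance to the other class, s_i piecewise as in the README.
The implementation is vectorized over the pairwise distance matrix and
is checked in tests against both an O(n²) brute-force loop and an
independent library implementation.

Training loop:

1. **Monitor split** (default 20%) is held out before seeding and fixes
   the indicator evaluation set for the whole run. When subject ids are
   present the split is group-aware — a participant's repeated
   measurements never straddle the boundary — and stratified by subject
   label, so both classes are always present on both sides.
2. **Seed** = top `seed_fraction` (default 10%, ⌈f·n⌉) of pool samples
   by silhouette width, selected *within* each class by
   largest-remainder proportional quotas with a floor of two per class.
   Global top-k could yield a one-class (untrainable) seed; the floor of
   two keeps every class's cohesion term a_i defined inside the selected
   population. The z-scaler is frozen here for the rest of the run.
3. **Streaming**: remaining pool samples arrive in a seeded random
   permutation, once each (rejected samples are not re-offered). A
   candidate's silhouette is computed against the current population
   *including itself* (configurable choice, documented); it must exceed
   the population's minimum s_i (gate 1). Below capacity the candidate
   is tentatively appended, at capacity it tentatively replaces the
   minimum-s_i member (ties broken toward the earliest-added member).
   The model is retrained on the tentative population and gate 2 applies
   on the monitor set: accuracy must not decrease AND precision or
   recall must strictly increase. Indicator comparisons are rounded at
   1e−12 so float noise cannot drive accepts; an undefined (0/0)
   precision or recall never counts as an increase when new, while any
   defined value counts as an increase over an undefined old one.
4. **Capacity** defaults to 60% of the pool (a cap is part of the
   procedure; its value is an open parameter, and 60% keeps the
   population well below full-data training while leaving room beyond
   the seed).

Monitor accuracy is non-decreasing by construction, and every commit is
replayable from the history log (`replay_history`), which records
s_candidate, s_min and all indicators before/after for every step.

A consequence of the strict-improvement gate worth knowing: on cleanly
separable data the seed model often already saturates the monitor
indicators, after which nothing further can be accepted — ATSS then
*is* the seed model. That is the intended behavior of the rules, and on
such cohorts ATSS matches full-data training on held-out folds; its
advantage appears when labels are noisy, where low-silhouette
(mislabeled) samples are filtered out of the population.

## Prediction with validity voting

Tissue magnitude spectra decay smoothly with frequency; a power law
y = a·x^b fitted in log-log space (closed-form least squares; r² of the
log-log regression) is the plausibility model for a single measurement.
Defaults: r² ≥ 0.90 to count as valid (threshold recorded in the
output), at least 5 of 10 measurements valid for any decision, and a
closed 80% agreement threshold among valid measurements (8/10 passes).
Invalid measurements are excluded from the vote rather than counted
against it — failed fits indicate acquisition artefacts, not biology. A
constant spectrum is an exact power law (b = 0) and is reported with
r² = 1. Anything below the agreement threshold, or with too few valid
measurements, returns "undefined" with the reason.

## Synthetic cohort

The generator reproduces the *statistical structure* the pipeline
assumes, with known ground truth; defaults mirror the study population:
53 subjects (34 female, 19 male), 20 diabetic, integer ages in [19, 76],
256 total measurements allocated near-evenly (44 subjects × 5 + 9 × 4,
i.e. ~5 each). Per subject:

- magnitude spectrum `|Z|(f) = a·f^b` with b ~ N(−0.15, 0.02); the
  coefficient is anchored so the 10 kHz magnitude is
  200 Ω · e^{N(0, 0.10)}, times `class_effect` (default 1.5) for
  diabetic subjects — the diabetic class has *higher* impedance (less
  conductive tissue). The power-law form is deliberately the same family
  the prediction stage's validity check assumes.
- phase is a smooth small negative curve −φ·√(f/f_max), φ ~ |N(0.12,
  0.02)| rad — a synthetic convention; the real phase marginals are
  unpublished, and no acceptance check depends on them.
- biometrics: diabetic subjects are older (+12 years on the draw floor)
  and heavier (+8 kg), mirroring the known risk-factor structure; sex-
  dependent weight/height normals.
- per-frequency multiplicative log-normal noise, default σ = 0.02,
  calibrated so repeated measurements of one subject show ~2% RSD (the
  device's observed repeatability); `stability_series` exposes exactly
  this check.
- `label_noise` flips the *recorded* label of that fraction of subjects
  (all their measurements; physiology untouched) — emulating
  well-managed diabetics and undiagnosed prediabetics whose samples
  mislead training.

Raw device readings are obtained by inverting the calibration transform
against a synthetic instrument response (gain falling 25% across the
sweep, a few degrees of phase drift), so the calibration path is
exercised end to end. Everything is deterministic given the spec seed;
the emitted CSV is byte-identical across runs.

What the generator does **not** emulate: Cole–Cole dispersion structure,
electrode-interface artefacts, within-day physiological drift, and any
correlation between biometrics and spectrum shape beyond the class
effect. Passing tests therefore demonstrate the pipeline's correctness
and the selection algorithm's behavior under the assumed structure, not
clinical performance on real patients.

## Evaluation protocol

30 repeats × 5 stratified folds (grouped by subject to prevent
leakage across a participant's repeated measurements) produce 150 paired
test-fold accuracies per method; pairing is by (repeat, fold), with the
fold shuffle and the ATSS streaming order derived from per-repeat seeds
spawned from the base seed. The paired lists feed a two-sided Wilcoxon
signed-rank test (exact enumeration up to n = 25 nonzero differences,
normal approximation with tie correction above — ties are frequent among
fold accuracies). Cohen's kappa is computed on pooled test predictions
per method. The silhouette summary reports the mean width of the full
training data, of the seeds, and of the final selected population,
averaged over runs. PCA (top-2 components of the standardized features)
is exposed purely as a visual diagnostic; no decision logic uses it.

Problem sizes used by the test suite and the acceptance script — the
256-sample default cohort, 30 × 5 comparisons, 200-instance silhouette
cross-checks, 100-repetition estimator recoveries — complete in well
under a minute each on a single CPU.

## Known limitations

- Binary classes only; the selection loop and kappa assume two labels.
- The scaler is frozen at seeding; a drifting population would not be
  re-standardized (deliberate: online rescaling would silently change
  the silhouette geometry mid-run).
- Whether a rejected sample might become acceptable later is untested by
  design — samples are offered once.
- The voting stage trusts the classifier's calibration only through the
  0.5 threshold; probabilities are reported but not aggregated.
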