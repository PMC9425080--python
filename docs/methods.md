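# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of `stablegait`.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal chain

A walking trial is a tri-axial trunk acceleration recording (g units,
anteroposterior / mediolateral / vertical, vertical positive up) covering
two 20 m directions joined by a turn.  Processing order is fixed as
tilt correction → low-pass filtering → direction splitting → event
detection.  Filtering before splitting does not change events on the
stationary walking segments, and splitting on the filtered signal makes
turn detection robust.

**Tilt correction.**  The mean acceleration vector estimates gravity;
a Rodrigues rotation aligns it with the vertical axis (mean horizontal
accelerations become exactly zero) and 1 g is subtracted from the
vertical channel.  A recording whose mean vector is below 0.5 g is
treated as already gravity-compensated and returned unchanged — this
makes the correction exactly idempotent — while a mean below 0.05 g on a
recording that should still contain gravity is rejected as free fall.

**Filtering.**  4th-order Butterworth at 3 Hz, applied
forward-backward (zero lag), on all axes.

**Direction splitting.**  The turn is the longest window (≥ 1 s) in
which the moving RMS of the vertical dynamics drops below 20 % of the
whole-recording RMS; the split point is its midpoint.  The first and
last 3 s of each direction segment are removed.

**Event detection.**  The vertical signal is smoothed by
cumulative-trapezoid integration (integration constant set so the
integrated series has zero mean, removing drift sensitivity), then
differentiated with a first-order Gaussian wavelet at a scale matched to
the dominant step frequency (spectral peak of the vertical dynamics in
0.5–4 Hz; `wavelet_scale` overrides).  The wavelet output's sign is
normalized against a finite-difference derivative so that initial
contacts are minima of the first derivative and final contacts peaks of
the second, independent of library sign conventions.  Physiological
gates: contacts closer than 0.25 s are merged through the peak-distance
constraint (the more prominent survives); inter-contact gaps above 2 s
raise a warning.  If a step interval contains no final-contact peak, one
is imputed at the median IC→FC offset so the IC/FC interleaving
invariant always holds; fewer than four initial contacts raise an
"insufficient strides" error.  Foot labels are arbitrary (F1 is the
first detected contact); the final contact between two initial contacts
belongs to the foot striking at the later one (the foot entering swing).

## Gait features

Step time = consecutive IC differences; stride time = same-foot IC
differences; stance = IC to the same foot's next FC; swing = FC to that
foot's next IC; double support = IC to the following FC; single support
= step minus double support.  Double/single-support features are
per-stride means.  Coefficients of variation use the sample (n−1)
standard deviation; cadence is 60 / mean step time, so Cd × StpT = 60 by
construction.  RMS is taken over the trimmed, gravity-free segment.

Step length uses the inverted-pendulum model: per step, the vertical
acceleration is double-integrated with linear detrending at each stage,
the displacement range h gives StepLg = 2√(2lh − h²) with pendulum
length l = 0.53 × body height and no multiplicative correction factor
(configurable choice; the correction constant differs between published
variants).  Gait speed is StepLg / StpT.

Dual-task costs use normal walking as the single-task reference —
the only task at preferred pace without a concurrent task — and are
computed per direction *before* the two directions are averaged, giving
16 STGF × 4 tasks + 16 DTC × 2 dual tasks = 96 measures.  Subjects with
any failed segment are dropped listwise with a logged reason.

The eleven feature-subset models are the four single tasks, the six
unordered task pairs and the all-task set; a model's columns include the
dual-task-cost columns of any dual task it contains.

## Cognitive index and groups

Each of the 12 measures is regressed on age and education in a normative
sample (OLS, per measure); timed measures (TMT) are negated first so
"worse" is one direction.  The residual covariance is the pooled OLS
residual covariance, shrunk toward its diagonal with an analytic
(Schäfer–Strimmer-type) intensity only when its condition number exceeds
1e6.  MDCog is the Mahalanobis norm of a subject's oriented residual
vector; it is affine-invariant in the measures and monotone in each
whitened coordinate.  Regression-based (rather than stratified) norms
are a declared choice; the upstream construction is not fully specified
in the source material.

Groups: 1-D k-means, k = 2, 1,000 restarts (restarts vectorized in a
Lloyd iteration; the best within-cluster sum of squares wins — verified
against scikit-learn's k-means), higher centroid = impaired; the healthy
cluster is split at age 60.

## Stable sparse classification

Defaults follow the stated protocol: 500 selection iterations, 70 %
subject and 70 % feature resampling (both stratified over the 62-vs-23
imbalance), screening to the top 50 % of offered features by absolute
Welch t statistic (the screening criterion is a declared stand-in; the
source describes it only as removing minimal-contribution variables),
consistency threshold 0.5 with strict >, labels coded 0/1 under the
squared-error objective as printed.  The selection-frequency denominator
is the number of iterations in which a feature was *offered* (survived
feature subsampling and screening), not the total iteration count.

γ defaults to 0.5; the λ path has 100 log-spaced values from λ_max down
to 10⁻³ λ_max with warm starts; λ is chosen by stratified 5-fold CV with
the **one-standard-error rule** by default.  The one-SE choice is a
deliberate parsimony default: with the CV-minimum rule, features that
correlate with the labels by chance *in the given dataset* are selected
whenever offered and can cross the 50 % threshold on pure-noise tables;
under one-SE, null stable sets are empty or near-empty while planted
d = 2 effects are still recovered with frequency ≈ 1.  Set
`one_se=False` for the CV-minimum variant.

Validation refits on stratified 70/30 splits with per-split CV for λ,
scores held-out subjects with φ0 + xᵀφ, and reports the median AUC,
pointwise 95 % ROC bands, and the operating point: the threshold with
the smallest pooled sensitivity ≥ the 90 % target, with specificity and
prevalence-weighted accuracy; a degenerate scorer yields the maximal
attainable point flagged `target_met=False`.  An empty stable set is an
explicit "no stable biomarkers" result, not an exception.  Features are
z-scored with training-portion statistics inside every resample.

All randomness flows from one root seed: stage names (and subject/task
identifiers) are hashed into a `numpy.random.SeedSequence` together with
the root seed, so any stage can be rerun in isolation and reproduce the
stream it saw in the full run.

## Statistical comparisons

The permutation two-way ANOVA computes classical proportional-design F
statistics for GROUP, TASK and their interaction on the subjects × tasks
layout, with a restricted permutation scheme: group labels permuted
between subjects (GROUP), task labels permuted within subjects (TASK),
and the interaction assessed on residuals after both main effects with
group labels permuted.  P-values use the add-one convention, so
p ≥ 1/(n_perm + 1).  Permutations are evaluated in vectorized batches.

Model comparison pools all per-model AUC samples, ranks them, and
compares mean ranks against a reference model with the normal
approximation for rank-sum differences, Bonferroni-corrected over the
non-reference models; confidence intervals use the Bonferroni-adjusted
normal quantile.  Being rank-based, the comparison is invariant to any
common monotone transform of the AUCs.

Baselines are an RBF-kernel SVM at default settings and shrinkage LDA
(lsqr solver, analytic shrinkage), evaluated with 10-fold × 500-rep
stratified cross-validation; both classifiers share identical fold
assignments within each repetition and standardization is fitted inside
every training fold.

## The synthetic generator

The generator emulates the study conditions, not human biomechanics.

**Cohort** (defaults): 40 YA (ages 22–38), 62 HE (60–88), 23 MCI-E
(61–87), with the published group means/SDs for age, height, weight and
sex ratio; education uniform 6–20 years, independent of group (no
distribution was stated).

**Cognitive scores.**  Twelve measures are linear in age and education
plus correlated residuals (compound-symmetric correlation 0.3).
Residuals are built in the whitened space of the normative covariance as
w = (shift + axial·ζ)·e₁ + rho·z, so each subject's population
Mahalanobis distance is controlled exactly.  The per-group constants
(YA shift 0, axial 2.0768, rho 0.6518; HE 0, 2.3064, 0.9293; MCI-E
8.6651, 1.4435, 1.0) were solved once by method-of-moments Monte Carlo
so the population MDCog mean/SD per group equal the study targets
(2.91 ± 0.97, 3.81 ± 1.08, 9.30 ± 1.65); the YA group *requires* a
sub-unit isotropic scale, since a central χ₁₂ distance cannot have mean
below 3.39.  MDCog computed through an *estimated* normative model is
inflated by a few percent relative to these population targets
(covariance estimation noise) — visible in the acceptance output.

**Acceleration.**  Each direction is a train of per-step waveforms (two
cosine harmonics of the step cycle, minimum at the step onset = initial
contact), step intervals i.i.d. with the profile's mean and CoV,
alternate-foot asymmetry on the durations, per-step amplitude jitter,
scaling such that the RMS after the 3 Hz low-pass equals the profile
RMS, a 3 s low-amplitude turn gap, gravity plus a random 1–5° static
tilt, and white sensor noise (default 100 Hz; no sampling rate was
stated for the hardware class).  Ground-truth final contacts are placed
at IC + 2 × double-support-fraction × step time.  Group profiles encode
the qualitative orderings (variability MCI-E > HE > YA; RMS, speed, step
length, cadence YA > HE > MCI-E) with lognormal subject-level and
task-level heterogeneity; magnitudes are free parameters chosen so the
HE/MCI-E discrimination is clear but non-degenerate (median validation
AUC typically 0.85–0.95, not 1.0) and dual-task interference grows with
impairment.

What the generator does **not** model: turning kinematics, sex-specific
gait, fatigue or learning across tasks, heteroscedastic sensor noise,
and any mechanistic link between the planted step length and the
waveform amplitude — the inverted-pendulum StepLg therefore recovers the
planted group *ordering* but not the absolute planted value.  Passing
tests show the pipeline recovers known structure from signals of this
class; they cannot certify performance on real IMU data.

## Numerical choices and limitations

- Coordinate descent converges at max coefficient change < 1e-7; Gram
  (covariance) updates with active sets; numba-compiled inner loop with
  a pure-Python fallback.  Agreement with brute-force lattice
  minimization (p ≤ 3) is within 1e-4 and with an independent solver
  within ~1e-6.
- λ_max for γ = 0 uses a 1e-3 mixing floor (ridge has no finite empty-
  model point); the ridge path endpoint therefore carries a small
  residual bias relative to OLS.
- The 3 Hz low-pass systematically shrinks detected step-time CoV by
  roughly 0.3–0.7 pp (more at fast cadence), because smoothing mixes
  adjacent step timings; recovery tests use planted CoV 3 % where the
  bias stays within 1 pp.  Wavelet-transform edge effects corrupt
  events within ~2 s of segment boundaries; the 3 s trim removes them
  in the pipeline, and tests compare events away from edges.
- k-means on MDCog is 1-D with k = 2; ties across restarts resolve by
  the first best inertia, and a tiny center perturbation breaks exact
  duplicate-initialization ties deterministically.
- The two-way ANOVA treats the repeated-measures layout with classical
  F statistics; calibration comes from the restricted permutations, not
  from sphericity assumptions (type-I error verified ≈ 0.05 under an
  exchangeable null with subject random effects).
- With all 96 synthetic gait features, shrinkage LDA is a strong
  baseline (the generator's class-conditional structure is nearly
  Gaussian and linear), so SSC's advantage there is in sparsity and
  interpretable stable sets more than raw AUC; SSC's AUC advantage is
  structural in the planted-sparse-signal setting.
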