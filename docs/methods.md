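# Methods

This note documents the models, conventions, and numerical choices behind
`mocapval`, and what the synthetic-data tests do and do not establish about
real recordings.

## Coordinate conventions and the frontal plane

All internal computation is in metres in a right-handed frame with the
vertical axis declared in each file header (default `z`); reporting uses
degrees, millimetres, centimetres, and dimensionless ratios as each
variable's convention dictates. Frames are 0-based and trim windows are
half-open `[start, end)`.

The frontal plane is subject-relative and re-derived **per frame**: its
medio-lateral (ML) axis is the unit hip-left→hip-right direction projected
into the ground plane, its second axis is vertical, and its origin is the
hip midpoint. "Medial" is resolved per side as the direction toward the
contralateral hip. This makes every planar measure invariant under global
translation and rotation about the vertical axis, which the test suite
asserts to 1e-9.

Sign conventions, mirrored across sides so left and right are comparable:
FPKA positive when the ankle lies medial to the knee; FPPA positive for
valgus (knee medial to the hip–ankle line); FPKD in millimetres with
medial *negative* (so FPPA and −FPKD agree in sign); the knee-varus proxy
positive for varus (knee lateral). All signed angles use atan2
constructions rather than bare arccos so values near 0° and 180° are
stable; ranges are (−180°, 180°].

The sagittal and varus angles are *joint-center proxies*: they use only
the eight joint centers, not a full marker-set biomechanical model, and
are applied identically to both systems. Their numerical comparability to
model-based varus values from marker systems is not claimed. Hip flexion
is measured in the plane orthogonal to the per-frame ML axis, anterior
resolved from the mean ankle→toe direction.

Rate matching is pure decimation (keep every k-th frame from frame 0, no
anti-alias filter): the downsampled reference samples stay bit-identical
to the originals, and no filtering is silently introduced into data that
is otherwise analysed raw.

## Event detection and measurement extraction

Squat trimming: the vertical hip-midpoint position is moving-average
smoothed (0.1 s window), twice centrally differenced, and compared with a
baseline from the first 0.5 s of quiet standing. Onset is the first run of
≥ 3 frames exceeding 5 baseline SDs (with an absolute floor of 1e-3 m/s²
guarding a zero-variance noise-free baseline), backed off by a 0.1 s
margin; the offset is symmetric from the reversed series. If no exceedance
is found the full window is returned with a warning flag rather than an
error. With appreciable white joint-center noise the second derivative is
noise-dominated and the trimmer deliberately falls back to the full
window; peaks and point frames are unaffected because the movement
dominates the series.

Jump events: per-foot ground levels are 5th-percentile heights of the toe
and ankle series; contact means a toe within 5 mm of its ground level;
toe-off is the last contact frame before the longest no-contact run. A
foot is flat when both its toe and ankle are within 10 mm of their own
ground levels, and full-foot contact is the first flat frame searched from
*mid-flight* onward — anchoring at mid-flight rather than at toe-off
prevents near-ground frames immediately after take-off from being mistaken
for a landing. All thresholds are exposed parameters with these defaults.

Knee flexion is the reference clock for every point definition, per
system: deepest squat is the knee-flexion argmax in the trim window;
mid-descent is the pre-argmax frame closest to half the peak (ties to the
earlier frame); landing impact is the full-foot-contact frame; deepest
landing is the knee-flexion argmax from contact to the trim end. Whether
"deepest landing" should be defined by knee flexion or hip height is
genuinely open; knee flexion was chosen by analogy with the squat
definition.

## Agreement statistics

* **LOA, repeated measures.** Differences d = test − reference (the
  orientation is a flag). The total SD decomposes by one-way ANOVA of d on
  subject, using the unbalanced-design correction
  n₀ = (N − Σnᵢ²/N)/(m−1) and clipping the between-subject component at
  zero. With one pair per subject this reduces *exactly* to classic
  Bland–Altman (asserted in tests). The multiplier is 1.96, not a
  t-quantile, matching the cut-off arithmetic.
* **ICC(2,1).** Computed from two-way ANOVA mean squares. A matrix whose
  total variance is at roundoff scale is reported as undefined (NaN)
  rather than as a ratio of numerical residue — this matters in the
  bootstrap, where resamples can draw one subject repeatedly. Sample
  estimates of the agreement form can stray slightly outside [−1, 1]
  when MS_C < MS_E; the classifier grades them monotonically instead of
  rejecting them.
* **Nested bootstrap.** Subjects with replacement, then one random trial
  per drawn subject; 10,000 resamples by default; the point estimate is
  the mean of the resamples (not the plug-in value) and the CI the
  2.5/97.5 percentiles. Undefined resamples are skipped and counted, with
  a warning above 10%. The resampling is fully vectorized
  (resamples × subjects × 2 arrays), so the default 10,000 costs
  milliseconds per cell.
* **RMC.** Each subject's two series are centered on their own means and
  the pooled centered values correlated — the ANCOVA partial correlation
  with subject as factor. Cross-checked against `pingouin.rm_corr` in the
  suite.
* **Mixed-model RMSE.** `statsmodels` MixedLM with a random intercept per
  subject (REML), reference regressed on test; RMSE from the conditional
  residuals so constant per-subject offsets are absorbed. Non-convergence
  (common when the subject variance is at the boundary) falls back to a
  fixed-intercept OLS with a warning.
* **Through-range LOA.** Per-frame series are autocorrelated, so LOA are
  estimated 100 times on k = 5 frames sampled uniformly without
  replacement from every trial, and the three limits averaged. "Five
  observations" is interpreted as five frames *per trial*, which preserves
  the subject/trial structure; per-subject or global subsampling were the
  alternatives. Trials shorter than k contribute all their frames with a
  warning. Through-range frames are paired over the intersection of the
  two systems' trim windows.

## Cut-off simulation

Per trial, 1000 true values are drawn, independent zero-mean Gaussian
errors with the two scenario SDs are added, and the half-width
1.96·SD(differences) is computed; the mean over 1000 trials is the
cut-point. The truth distribution cancels in the differences (asserted by
a same-seed test at truth SD 0 vs 100), and observations within a trial
are i.i.d., so the plain SD — no repeated-measures correction — is
correct here. The assumed reference error SDs are 5° for the angle family,
0.2 for the separation ratios, and 15 mm for FPKD; system B gets 1.0/1.5/
2.0 times the reference SD. Grading bands are strict upper bounds (a span
exactly at a threshold falls in the worse grade); ICC bands are
left-closed at 0.5/0.75/0.9.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: 14 children, height
~ Normal(109.2, 7.9) cm truncated to [80, 140], three trials per movement,
a 200 Hz reference system and a 50 Hz test system. Segment lengths follow
fixed anthropometric fractions of stature (pelvis width 0.145 h, thigh
0.245 h, shank 0.246 h, foot 0.152 h). Movement profiles are smooth
cosine-bell splines — not physics simulations — because the statistics
under test depend on error structure, not dynamic realism. Per-subject
style parameters (squat depth ~ N(120°, 12°), jump distance
~ N(0.77, 0.20) m, valgus tendency ~ N(8, 10) mm) create the
between-subject variance the reliability statistics need; jump flight time
scales with jump distance (plus trial noise) so that stronger jumpers also
rise higher, giving jump height realistic between-child spread. The
flight phase is exactly ballistic (the whole body translates rigidly along
a parabola under 9.81 m/s²), the forward travel is set so the *defined*
jump length — inter-ankle midpoint at toe-off to a single ankle at
contact — equals the subject's jump-distance parameter, and feet stay
flat on the ground outside flight.

Error models per system: isotropic Gaussian joint-center noise; a
posterior hip-center bias that ramps linearly from full weight at 0° knee
flexion to zero at 30° (the markerless-system failure mode near full
extension; the ramp shape is a modelling choice, as only the phenomenon
is documented); and, on jumps, a damped medio-lateral knee-center
oscillation triggered at toe-off and landing (amplitude in degrees
converted through the shank length, cosine onset so the first excursion
carries the full amplitude, default 8 Hz, 0.25 s decay) — the
thigh-wand-wobble failure mode of marker systems. The magnitudes of the
hip bias and wobble are free parameters of the error profile, not
estimates of any real system. Default study-condition profiles: reference
200 Hz, 3 mm noise, 10° wobble; test 50 Hz, 5 mm noise, 15 mm hip bias.

Because the noise is temporally white, it is *harsher* on
acceleration-domain algorithms than real capture noise (which is smooth);
passing tests therefore show the statistics and event logic are correct
under known error structure, not that any specific real system would
achieve the same agreement grades. Soft-tissue artifact dynamics, camera
models, and marker placement error are not modelled.

## Problem sizes and determinism

Defaults were chosen so a full pipeline run (14 subjects × 3 trials × 2
movements, 10,000 bootstrap resamples, 100 through-range estimates,
1000 × 1000 cut-off simulations) completes in well under a minute on one
core; the test suite uses reduced designs (e.g. 200-resample bootstraps,
50 × 200 simulations) where the full scale adds nothing to the property
being checked, and the acceptance checks run the cut-off simulation at
the full design. Every stochastic stage takes a named seed derived from
the run seed via `SeedSequence`, and a rerun with the same configuration
writes byte-identical tables (asserted in the suite).

## Known limitations

* The varus proxy and sagittal angles are joint-center constructions;
  values are not numerically comparable to marker-model outputs.
* The squat trimmer assumes ≥ 0.5 s of quiet lead-in and degrades to the
  full window under heavy white noise (flagged, not silent).
* TRC reading covers the standard header and millimetre/metre units only;
  C3D, force plates, gap filling, and marker-level data are out of scope.
* Time alignment of the paired systems is assumed done upstream; the
  generator emits aligned pairs and an integer frame offset is the only
  supported correction.
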