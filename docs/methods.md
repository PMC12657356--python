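# Methods

This note documents the models, parameter choices and numerical decisions in
`skimech`, what the synthetic generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All positions are stored in millimetres (motion-capture convention); derived
areas are reported in m², angles in degrees, power in watts per trial channel
and W·kg⁻¹ after mass normalization. The aligned frame is pelvis-fixed:
x forward, y to the skier's left, z up.

## Preprocessing

**Pelvis alignment.** The pelvis basis is built per frame from three points:
origin (sacral), left and right ASIS. y is the unit leftward ASIS axis; x is
the anterior vector (mid-ASIS minus origin) orthogonalized against y; z
completes the right-handed triad. The whole cloud is rotated by the inverse
(transpose) of this proper rotation, so the pelvis axes coincide with the
output axes at every sample and heading changes vanish. Collinear or
coincident pelvis points raise an error naming the first bad frame.

**T12 referencing** subtracts the T12 position per frame; being a rigid
translation it commutes with the alignment rotation (asserted in tests).

**Segmentation.** The signal is the Euclidean norm of left-toe displacement
about its *trial-mean* position in the aligned frame. The displacement
reference (trial mean rather than cycle start or previous frame) is a package
decision: a fixed reference is the only reading under which a 1 cm threshold
is meaningful across techniques. Peaks are found with three guards:

* height ≥ 10 mm (the 1 cm rule);
* prominence ≥ 5 mm — the norm rides at a ~100–200 mm baseline, so a bare
  height threshold would admit noise-scale wiggles; half the threshold is a
  package choice, not a tuned value;
* a two-pass minimum inter-peak distance of 0.25 × the median inter-peak
  interval from a first height-only pass, suppressing noise doublets.

The norm is smoothed with a centered 0.1 s moving average before peak
detection; a symmetric window does not displace symmetric peaks. Whether
trial-edge peaks were kept in the original protocol is unknown; here edge
samples cannot be peaks by construction of the detector.

**Time normalization** resamples each inter-peak segment (including the
closing peak sample) to 101 evenly spaced points with SciPy's
`PchipInterpolator` per channel. PCHIP needs ≥ 4 support samples; shorter
segments and segments longer than 10 s (glide/rest, not propulsion) are
discarded with a logged warning.

**Cadence.** Per-skill duration distributions are compared with a one-way
ANOVA; when every duration is identical the F test is undefined and p = 1 by
documented convention (zero between- and within-group variance is no evidence
of a difference).

## Cycle database and PCA

Rows are cycles; the 23,432 columns are 101-sample blocks ordered
`[time | x(76) y(76) z(76) | power upper, lower(knees), RTA]`. The time block
is the *un-normalized* time axis (0..duration), so cadence enters the
decomposition. Power channels are divided by body mass (W·kg⁻¹) and shoulders
(knees) are summed bilaterally into the upper (lower) channel; RTA stays
separate in the database and is added to the lower-body total only at the
metrics stage.

Amplitude normalization multiplies each unit block by a single scalar so its
pooled min-to-max range equals the coordinate block's range; scalars are
stored and exactly invertible. A zero-range block keeps scalar 1 with a
warning.

PCA is the SVD of the column-mean-centered matrix — no per-column
standardization (the block scaling already reconciles units, and
standardizing 23k columns would inflate flat channels). Whether the original
analysis additionally standardized columns is unstated; this package does
not, and flags the choice here. Loadings are sign-fixed so each one's
largest-magnitude element is positive, making score signs — and therefore the
95th/5th percentile tail choice — reproducible across runs. Explained
variances come from the singular values; retention keeps the smallest K whose
cumulative percentage reaches the threshold (default 90%), with a small
(1e-9) tolerance against floating-point shortfall.

**Multi-component reconstruction.** For each selected PC the elite avatar
uses the 95th percentile of the score distribution when the PC increases with
skill and the 5th when it decreases; the beginner avatar takes the opposite
tails. Percentiles are computed over *all* cycles (not per skill group — the
original choice is unstated; all-cycles is flagged here) with linear
interpolation between order statistics. With no selected PCs both avatars are
the mean cycle (warned). Reconstruction is linear, so mirrored scores give
reflections about the mean (asserted).

## Sub-technique classification

A degree-2 polynomial-kernel SVM — the *inhomogeneous* kernel
(γ·x·y + 1)², since the homogeneous variant cannot separate sign-symmetric
score clusters — with per-column standardization and C = 1, over the retained
PC scores. The validation protocol behind the original headline numbers is
unstated; this package defines its own: a seeded, class-stratified held-out
split for the headline figures, stratified k-fold cross-validation on the
labelled subset reported alongside, and resubstitution reported separately.
The macro one-vs-rest ROC AUC uses trapezoidal integration per class
(verified in tests against the Mann–Whitney U identity); the "unknown"
catch-all trains as an ordinary class but is excluded from the macro AUC by
default. Classes need ≥ 3 labelled examples to train; cross-validation folds
that would drop a class below that minimum are skipped with a warning.

## Skill statistics

Per retained PC: a fixed-effects one-way ANOVA of scores on the four-level
skill factor (computationally `scipy.stats.f_oneway`, identical to a GLM with
one categorical regressor; verified against a brute-force sum-of-squares
oracle). "Stepwise" is formalized as *strict* monotonicity of the four group
means in skill order — ties break it; the sign of the trend is the PC's
direction. Selection = significant (raw p < 0.05, matching the
reported-table convention) AND stepwise. A Holm-adjusted p column is reported
for transparency but does not drive selection. Cycles are treated as
independent observations; with few athletes per skill group this
pseudo-replicates and the p-values are anti-conservative — the report logs
this caveat rather than silently switching to a mixed model.

Violin data uses a Gaussian KDE per group with a documented bandwidth floor
(1e-3 of the pooled scale) for degenerate single-point groups.

## Derived metrics

**Frontal area** is the sum of two rectangles in the frontal plane:
(mediolateral extent × vertical extent) of the upper-body points plus the
same for the lower-body points, equipment excluded, extents as max − min.
The source description of the rectangles is internally ambiguous (it names
mediolateral and anteroposterior extremes); drag-relevant frontal area is
geometrically ML × vertical, which is what this package computes — the
anteroposterior wording is read as describing which extremes of the cloud
bound the boxes. **Ski angle** is the signed transverse-plane angle of the
tip-minus-tail axis against the forward axis, positive toward +y; a
near-vertical ski (transverse projection < 1 mm) yields NaN and is skipped
with a warning. **Power**: upper = both shoulders; gross lower = both knees
+ RTA; mass normalization is homogeneous of degree −1 (asserted).

## Track reconstruction

Laps are segmented at recurrent closest approaches to the start point: after
leaving a 2×-radius hysteresis band, the next in-gate window's distance
argmin is a lap start (gate radius default 5 m; a final in-gate return closes
the last lap rather than starting a new one — candidates within half a median
lap of the data end are dropped). Receiver drift is estimated as the
least-squares line through the lap-start positions — the same physical gate,
so any linear trend there is drift, never track shape — and subtracted from
the whole series; each lap is then demeaned, resampled to 400 equal
arc-length points and averaged. Demeaning is idempotent and the
reconstruction is invariant to a global position offset. Limitation: drift
accumulating beyond the gate radius within the recording defeats recurrence
detection (laps are then missed); the gate radius can be widened per run.

## The synthetic skier

The generator's purpose is to emulate the *statistical structure* the
pipeline assumes — not musculoskeletal realism. No ground-reaction forces, no
snow friction, no muscle models; and the per-technique kinematic amplitudes
are invented defaults (no published kinematic equations exist for these
techniques), chosen once for plausible ranges.

* **Skeleton**: a 76-point upright template (documented in `simulate.py`),
  metres internally, millimetres on output.
* **Limb templates**: 1–3 harmonics per chain with technique-specific phase
  offsets. Diagonal stride: contralateral arm/leg phases; double pole:
  bilateral symmetric arm sweep with trunk crunch and quiet legs; kick double
  pole: symmetric arms plus a single-leg kick; skating: leg loops tilted 40°
  out of the sagittal plane (frontal-plane push) with externally rotated
  skis; glides: near-quiet limbs, with the free glide tucked (upper body
  compressed vertically to 55%).
* **Segmentation signal by construction**: the left toe rides a limaçon
  r(θ) = r0 + a·cos θ. The distance of such a loop from its centroid is
  r0² + a·r0·cos θ + a²/4 — exactly one maximum per revolution — so a trial
  of n cycles has exactly n toe-displacement peaks, with technique-specific
  r0/a (e.g. 150/100 mm diagonal stride, 50/20 mm glides). The skating tilt
  is a rigid rotation of the loop plane and preserves this property exactly.
  Ground-truth boundaries are the per-cycle argmax of the clean signal.
* **Cycle durations**: per-cycle periods are Gaussian with configurable mean
  (default 1.0 s, roughly the per-trial mean of published elapsed-time /
  cycle-count ratios) and CV (default 8%), floored at 0.3× the mean.
* **Joint power**: nonnegative von-Mises-shaped pulses phase-locked to the
  cycle, channel-specific peaks and phases per technique, scaled by effort
  (×0.8 / 1.0 / 1.2 for easy/medium/hard) and by skill gains.
* **Skill effects** (per rank step over beginner=0 … elite=3, defaults):
  upper power ×1.25, lower power ×1.15, mediolateral body width ×0.93
  (frontal-area proxy), ski external rotation −4° (floored at 1.5°); plus a
  skill-dependent technique mix (beginners diagonal-stride-heavy; double pole
  and skating grow with skill). Small per-cycle lognormal jitter (σ = 5%)
  keeps realized effects stochastic.
* **Noise**: band-limited (~10 Hz) Gaussian positional noise drawn *per rigid
  segment cluster*, not per point — the suit tracks one inertial sensor per
  segment, so positional error moves a segment's points together. Per-point
  i.i.d. noise would fabricate pelvis-orientation jitter that the alignment
  step amplifies (≈1° of pelvis noise → ≈20 mm of spurious toe motion at a
  1 m lever arm), a failure mode real sensor fusion does not produce. Default
  2 mm SD. Drift is a single linear common-mode ramp (default 5 mm/s), which
  T12 referencing removes by design. Power channels are noise-free (they are
  synthetic model outputs, not force-plate measurements).
* **GNSS**: a 2:1 oval scaled to the requested lap length (Ramanujan
  perimeter approximation), sinusoidal elevation of amplitude half the
  requested change, per-sample Gaussian noise and a linear drift ramp.

**What a green test does and does not establish.** The synthetic world is
low-rank (a handful of harmonics), so its PCA retains ~4 components where a
field dataset retained 17; classifier accuracy and AUC on the synthetic
cohort are scaled analogues, not reproductions, of field results. Green
pipeline tests establish that the algorithms recover effects *known to be
embedded*; they say nothing about effect sizes in real skiing data.

## Controlled experiment designs

`pipeline.run_skill_contrast` holds technique (skating) and effort (medium)
constant so that skill is the only systematic gradient. Two confounds
motivate this, both visible in mixed cohorts: (1) composition — higher-skill
groups skate more, and skating's wide stance and large base ski yaw dominate
the frontal-area/ski-angle contrast with the *opposite* sign of the
within-technique effect; (2) effort — mixed efforts create a common
power-amplitude variance axis that absorbs the lower-power skill gain,
leaving the stepwise PC an upper-vs-lower contrast. Holding both constant is
standard experimental control; the generator's effect sizes are identical in
every experiment. `pipeline.run_classification_experiment` keeps the full
mixed cohort, where technique diversity is the point.

## Defaults at a glance

| parameter | default | where |
|---|---|---|
| sample rate | 240 Hz | SimConfig |
| segmentation threshold | 10 mm (peaks), 5 mm prominence | preprocess |
| smoothing window | 0.1 s | preprocess |
| cycle samples | 101 | preprocess |
| min/max cycle | 4 samples / 10 s | preprocess |
| PCA retention | 90% cumulative variance | pca |
| significance level | 0.05 (raw p) | stats |
| MCR percentiles | 5 / 95, all cycles | pca |
| SVM | poly degree 2, coef0 1, C 1, standardized inputs | classify |
| GNSS gate radius | 5 m | track |
| lap resampling | 400 arc-length points | track |
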