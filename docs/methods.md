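# Methods

`fmscore` implements automated scoring of 13 upper-extremity Fugl-Meyer
Assessment (FMA) motor items from depth-camera skeletal trajectories, plus a
dimensionless movement-smoothness statistic. This note records the models,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## Data model

A recording is one FMA item attempt: a 30 Hz sequence of frames, each with a
timestamp and ten upper-body joints (head, shoulder center, left/right
shoulder, elbow, wrist, hand) in 3-D camera coordinates — 31 scalars per
frame. The on-disk format is delimited text, one frame per row, with
optional `#` metadata headers. Because no public specification of the
sensor's text export exists, the column order, delimiter and units are
declared in a `Dialect` config (YAML/JSON) and default to: time first, then
joints in the canonical order, each as x,y,z, meters and seconds.

A cohort table holds, per subject and side: therapist scores (0/1/2) for the
13 items, the 13-item sum (0–26), the full 33-item upper-extremity total
(0–66), the Brunnstrom arm stage (1–6) and a hemiplegic-side flag. Rows
violating invariants are flagged in a validation report, never silently
dropped.

## Preprocessing

1. **Mirroring.** Right-arm recordings are reflected through the sagittal
   plane — approximated as the vertical plane through the first-frame
   shoulder center with normal along x — and left/right labels are swapped,
   so both arms share one coordinate frame for learning. No torso
   re-orientation is applied. Reflection preserves inter-joint distances
   exactly.
2. **Resampling.** Irregular timestamps are linearly interpolated onto the
   nominal rate; downstream finite differences assume uniform sampling.
3. **Clipping.** Still frames before/after the motion are removed by
   thresholding the per-frame displacement of the moving hand, divided by
   the body-segment length (so the threshold is dimensionless and the whole
   pipeline stays scale-invariant), smoothed with a 5-frame moving average.
   Defaults: threshold 0.2 % of body length per frame, 5-frame margin kept
   on each side; all four constants are exposed. The rule uses the hand
   joint by default (`joint="max"` switches to the max over joints — the
   alternative reading of "joint distance between frames"). A recording
   with no frame above threshold is rejected with a *no motion detected*
   error; the pipeline wrapper can instead keep the whole recording, since
   a genuine score-0 attempt contains no motion yet still must be scored.
4. **Pose normalization.** All joints are translated by minus the
   shoulder-center position at the first (clipped) frame and divided by
   L = |wrist−elbow| + |elbow−shoulder| + |shoulder−shoulder center| of the
   moving side. L is averaged over frames to damp sensor jitter (a
   first-frame-only option exists). The result is dimensionless and
   invariant to seating position and body size.

## Smoothness: dimensionless normalized jerk

The movement vector P(t) stacks the six moving-side joints (18 dimensions).
With jerk the third time-derivative,

    NJ = sqrt( 1/2 * ∫_{T1}^{T2} ||d³P/dt³||² dt * duration⁵ / length² )

where duration = T2 − T1 is the clipped window and length is the maximum
Euclidean displacement of P(t) from its value at T1 (a `length_joint="hand"`
option restricts the length scale to the hand joint — the other reading of
the ambiguous phrase). The ½ factor sits inside the square root, following
the displayed formula literally. A 1-D minimum-jerk reach
x(t) = D(10τ³ − 15τ⁴ + 6τ⁵) has ∫jerk²dt = 720 D²/T⁵ and therefore
NJ = √360 ≈ 18.97 for any D and T: this closed form is the analytic anchor
of the test suite. NJ is invariant under uniform spatial scaling and time
dilation by construction.

Numerics: the third derivative uses second-order finite differences — the
five-point central stencil in the interior and one-sided second-order
stencils at the two boundary frames on each end — so the series keeps the
full frame count and the integral covers all of [T1, T2]. This matters
because a point-to-point reach has its largest jerk exactly at the movement
boundaries; discarding boundary frames (as a repeated-central-difference
stencil would force) biases NJ low by ~2.5 % even at 300 Hz. Integration is
trapezoidal. At least 7 frames are required.

For real sensor streams the `smooth=True` path first applies a zero-phase
4th-order Butterworth low-pass at 3 Hz. Triple differentiation amplifies
broadband jitter by ~fs³, and at 30 Hz no short polynomial (Savitzky-Golay)
window attenuates it adequately; a frequency-domain cutoff is the
appropriate tool. Voluntary reaching keeps its energy below ~2 Hz, so the
movement's own jerk is preserved; 4–10 Hz pathological tremor is strongly
attenuated in *position* but remains the dominant — and monotone — jerk
contribution because jerk scales with frequency cubed. The default path
(`smooth=False`) applies no filtering at all, so analytic oracles are
checked against a pure stencil.

Cohort comparisons use log10(NJ); the log transform symmetrizes the heavily
right-skewed NJ distribution. Base 10 is the default (configurable): the
smooth-reach floor log10 √360 ≈ 1.28 then sits near reported healthy-side
values, whereas a natural log would not.

## Scoring: features → PCA → ANN

**Features (~100 per recording).** Summary statistics {min, max, range,
variance, mean} of a fixed, versioned roster of 20 time series: 4 joint
angles (elbow; shoulder vs trunk; wrist; whole-arm elevation), 7 joint
distances (hand–shoulder, hand–head, elbow–head, hand–shoulder center,
wrist–head, wrist–shoulder center, elbow–shoulder center) and per-axis
displacements of hand, wrist and elbow; plus the frontal-plane bounding
rectangle area of the hand path, the normalized jerk and the movement
duration — 103 features. Range/variance features carry most of the signal
because range of motion grows with the FMA score. "Bounding area" is
ambiguous; both readings (per-series range, and the 2-D bounding rectangle)
are provided as named features. The roster is identical across items and
pinned by a version string stored with every trained model.

**Per-item predictor.** Features are standardized (zero mean, unit
variance), reduced by PCA to k ∈ [4, 10] components (component signs fixed:
largest-magnitude loading positive), and classified by a small feed-forward
network identical across items: one hidden layer of 16 logistic units,
3-way softmax output, L2 penalty 1e-3, L-BFGS, ≤2000 iterations, seeded.
Ties in the argmax resolve toward the lower score (conservative clinical
choice). A single-class training set yields a constant predictor. `select_k`
picks k by inner cross-validation, ties toward smaller k; the bundled
recovery experiment fixes k = 8 for determinism.

**Imbalance and validation.** Real cohorts have skewed score
distributions, so minority classes are randomly oversampled with
replacement up to the majority count — inside training folds only.
Cross-validation is 8–10-fold (default 10), stratified when every class has
at least k members, plain shuffled otherwise; standardization and PCA are
refit inside every training fold so no test information leaks. Item
accuracy is the fraction of exact score agreements.

**Cohort evaluation.** Per-subject 13-item sums of predictions are
correlated (Pearson) with the therapist 13-item sums and with the 66-point
full total; hemiplegic vs non-hemiplegic log jerk is compared with a paired
t-test; hemiplegic log jerk vs Brunnstrom arm stage uses Spearman's ρ on
the stage-3–6 subgroup (below stage 3 the flexion-synergy motion is largely
absent and the smoothness statistic measures noise).

## Synthetic data generator

The generator exists so the entire pipeline is testable without patient
data. One attempt is built as follows: item-specific start/end wrist
targets (all comfortably inside the 0.54 m two-link reach) define endpoint
arm poses via exact two-link inverse kinematics (upper arm 0.28 m, forearm
0.26 m, half-shoulder 0.18 m); a single minimum-jerk profile then carries
every joint along its chord between the two poses. The noise-free 18-dim
trajectory is therefore exactly minimum-jerk with NJ at the √360 floor —
matching the empirical observation that unimpaired test motions score near
that floor. The chord shortcut lets segment lengths sag by a few
centimeters mid-path; per-frame rigid inverse kinematics was measured to
inflate NJ of clean motions to 30–70 through the kinematic nonlinearity,
which would misrepresent unimpaired movement, so plausibility of the pose
was traded for fidelity of the smoothness statistic.

Degradations: (i) band-limited Gaussian tremor (4–10 Hz, within the 15 Hz
Nyquist), enveloped by the movement speed profile (intention-type tremor),
applied with distal weighting hand 1.0 / wrist 0.8 / elbow 0.4; (ii) slow
sensor drift (2 mm RMS below ~0.3 Hz) plus broadband jitter (0.3 mm RMS) on
all joints — the error structure of an SDK-smoothed skeleton stream, whose
dominant error is a slowly wandering joint estimate rather than white
frame-to-frame noise; (iii) 1 s of still padding on each side; 30 Hz
timestamps.

Score classes map to movement amplitude (class 0: 0–20 % of full range,
class 1: 30–70 %, class 2: 80–100 %) and slower tempo with impairment;
tremor amplitude maps inversely onto the Brunnstrom stage (12, 10, 8, 5.5,
3.5, 2 mm RMS for stages 1–6; 0.3 mm on the non-hemiplegic side). A cohort
pairs a hemiplegic side (class- and stage-dependent) with a non-hemiplegic
side (full amplitude, minimal tremor) per subject; the requested per-item ×
class counts are met exactly, stages alternate within each class band, and
the 66-point total is synthesized consistently with the 13-item sum.

What the generator does **not** emulate: occlusion and tracking loss,
compensatory trunk motion, stereotyped synergy coupling between joints,
forearm rotation (untracked below the wrist), and score-dependent movement
*quality* beyond amplitude/tempo/tremor. Passing tests therefore show that
the pipeline recovers scores when amplitude and smoothness carry the signal,
not that it reaches any particular accuracy on clinical data.

## Problem sizes and determinism

The recovery experiment uses 70 recordings per item and class (210 per
item, 13 items) with 10-fold CV — large enough that fold accuracies are
stable, small enough to run in well under a minute on one CPU. All
randomness (cohort draws, fold shuffles, network initialization,
oversampling) derives from a single integer seed; identical seed, config
and inputs reproduce every report bit-for-bit.

## Known limitations

- The clipping rule and the ~100-feature roster are this package's concrete,
  documented choices for procedures that have no public reference
  definition; both are config-exposed/versioned rather than claimed
  canonical.
- The ANN hyperparameters are small-sample defaults, not tuned values.
- NJ for multi-joint curved movements has no unique "floor"; the √360
  anchor applies to straight-path minimum-jerk motion.
- With fewer than ~7 frames after clipping the jerk statistic is undefined;
  extremely hypokinetic attempts fall back to full-window analysis where
  the displacement, not the jerk, carries the information.
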