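# Methods

## Coordinate and angle conventions

Landmarks arrive in hip-centered normalized image coordinates: x positive to
the image right, y positive downward, z an estimated depth with smaller
values closer to the camera. All features are invariant to global
translation (only coordinate differences enter) and to uniform scaling of
all coordinates (ratios, angles, and the trunk-size terms are homogeneous of
degree zero). Angles are degrees in [0, 180] everywhere; the cosine passed
to `acos` is clamped to [−1, 1] so numerically (anti)parallel vectors cannot
produce NaN. Planar ("2D") angle variants drop z; "3D" variants keep it.

## The feature set

Right-side definitions (left mirrors with sides swapped):

| feature | definition |
|---|---|
| `rtarm_distratio` | \|shoulderR→elbowR\| / \|shoulderR→hipR\| |
| `rtelbowhip_distratio` | \|elbowR→hipR\| / \|shoulderR→hipR\| |
| `rthip_distratio` | \|shoulderR→hipR\| / \|hipR→hipL\| |
| `rtshoulder_distratio` | \|shoulderR→shoulderL\| / \|shoulderR→hipR\| |
| `rtshoulderAbduction` / `_3Dabduction` | angle between shoulderR→elbowR and the downward trunk midline (mid-shoulder→mid-hip), 2D / 3D |
| `rtshoulderAngle` / `_3Dangle` | angle at shoulderR between rays to elbowR and hipR, 2D / 3D |
| `rt_uppertrunkAngle`, `rt_lowertrunkAngle` | interior angles of the shoulders–hips quadrilateral at shoulderR / hipR |
| `rt_faceAngle` | angle at the nose between the ray to the right ear and the ray to the shoulder midpoint |
| `rt_trunksize` | \|cross2d(shoulderR→shoulderL, shoulderR→hipR)\| / (2D \|shoulderR→hipR\|)² |

Two conventions here were genuinely open design choices:

- **Abduction reference axis.** The abduction angle is measured against the
  trunk *midline* (mid-shoulder → mid-hip) anchored at the shoulder rather
  than the per-side shoulder→hip ray. Against the per-side ray the feature
  would be identical to `rtshoulderAngle`; against the midline the two
  genuinely differ under the projection shear an oblique camera induces,
  which is why both families carry signal. On a frontal view of an upright
  trunk the midline is vertical, so the planar abduction equals the true
  anatomical angle exactly (see the angle-preservation property below).
- **Trunk and face angles.** "Upper/lower trunk angle" is read as the four
  interior angles of the shoulders–hips quadrilateral — the only
  non-degenerate reading that yields distinct right/left variants. The face
  angle puts its vertex at the nose with rays to one ear and to the shoulder
  midpoint: side-specific, robust, and monotone in camera yaw (the property
  the camera model relies on).

Degenerate geometry (zero-length trunk, coincident hips) raises an error
naming the offending feature instead of emitting NaN, so corrupted frames
are dropped explicitly upstream.

## Synthetic data generator

The generator emulates a standing-subject abduction study: per subject a
parametric skeleton (height Gaussian, mean 166.3 cm, SD 8.1 cm, truncated to
[145, 195]; segment fractions of height with ~4 % log-normal inter-subject
jitter; hips at 0.53·h), right arm abducted 10–160° in 10° steps within the
coronal plane with a straight elbow, left arm hanging. A pinhole camera on a
3 m circle at 1.5 m height (vertical FOV 65°) aims horizontally at the trunk
center; yaw defaults are {−30, −15, 0, 15, 30, 45}° — positive toward the
subject's right, −45° excluded as in typical protocols because the elbow can
leave the frame. Defaults produce 10 × 6 × 16 × 20 = 19,200 frames; every
frame's noise stream derives from the master seed, so generation is fully
deterministic.

Numerical projection choices:

- **Isotropic image units.** Both image axes share the image-height scale
  (no per-axis aspect normalization), so projecting a fronto-parallel plane
  is a similarity transform. Consequence: at yaw 0 with the arm in the
  coronal plane, `rtshoulderAbduction` equals the true abduction angle to
  floating-point precision across the whole grid — the simulator's central
  correctness anchor.
- **Depth channel.** z = f·(depth − mid-hip depth)/(mid-hip depth), i.e. the
  same angular units as x and y, multiplied by a depth gain of 0.5. The gain
  emulates the systematic flattening of monocular depth estimates: with
  full-scale depth, 3D segment lengths would be rotation-invariant and a 3D
  feature alone would trivially solve camera invariance, which matches
  neither how estimated depth behaves nor the motivating observation that 3D
  lengths shrink under foreshortening. z stays scale-free.
- **Stylized head.** Nose 0.6·d forward of the head center and ears 0.8·d
  lateral, 0.2·d above nose level (d = head offset, 0.13·h). These offsets
  place the geometric fold of the nose–ear ray outside the camera-yaw range,
  making both face angles strictly monotone in yaw over [−30, 45]° for the
  entire simulated cohort; an anatomically proportioned head provably folds
  inside that range under this face-angle definition.

Noise model (`NoiseSpec`): additive Gaussian jitter on x, y (σ = 0.003
normalized units) and on z (3σ), plus a systematic detection drift for the
raised right arm of magnitude b = 0.004·(θ/160) + 0.003·(|yaw|/45): the
right-shoulder landmark drifts medially (0.75·b) and downward (0.5·b), the
elbow follows that drift rigidly and is additionally pulled toward the
shoulder by b (apparent arm shortening). The drift directions implement the
occlusion-smear mechanism — detection blurs toward the trunk when the arm
covers the shoulder region — and reproduce the characteristic correlation
sign pattern of real pose-estimator output: abduction angles and the
elbow–hip ratio correlate positively with the true angle, while the arm,
shoulder and hip length ratios correlate negatively.

What the simulator does **not** emulate: garment/body-shape confounds,
frame-to-frame temporal correlation of detector error, occlusion dropouts,
left-handed or non-standing subjects, and any photometric effect. Passing
tests therefore demonstrate the pipeline's correctness and its robustness to
the modeled error structure, not clinical accuracy on human video.

## Models and training

Regressor families: ordinary least squares (exact minimum-norm solution) and
gradient-boosted trees (LightGBM: 500 rounds, learning rate 0.05, 31 leaves,
min 20 samples/leaf; single-threaded deterministic training so a seed pins
the model bit-exactly). Splitting defaults to frame-random 80/20; a
subject-grouped mode is provided because random splitting of video frames
leaks near-duplicate frames between partitions — the frame-random default
mirrors the common protocol, the grouped mode is the honest generalization
test, and the pipeline records the training subjects so leakage is
assertable.

Two-stage training splits once, fits the camera model on the training
partition only, augments both partitions with its predictions
(`estimate_camAngle`), fits the abduction model on the augmented training
rows, and reports on held-out rows that neither stage saw. The stage-3
feature set defaults to the right-arm geometry block plus
`estimate_camAngle`; an `all-bilateral` mode feeds every feature instead.
Predictions are clipped to [0, 180]°.

The camera model is a regression (its natural MAE reporting); treating yaw
as a class label is out of scope. Its MAPE is undefined whenever the 0° yaw
is present, so reports carry MAE as the headline with an explicit
"undefined" note rather than a silent NaN.

## Evaluation

R² = 1 − SS_res/SS_tot; MAPE = mean(|y−ŷ|/|y|)·100 (the standard absolute
percentage form), raising a metric-undefined error when any true value is
zero unless the caller opts into an annotated report; MAE; Pearson r.
Permutation importance shuffles one column at a time (fresh seeded
permutation per repeat, other columns untouched) and reports the mean ± sd
score drop; for the MAE metric the sign is flipped so larger always means
more important. By default importances are computed on the test partition;
the caller chooses the table, so either partition works. Perfectly collinear
duplicates share and therefore shrink importance — documented behavior, not
a bug. Note one calibration fact: permuting a feature that a model copies
verbatim drives r² to about −1 (residual variance doubles), so the maximum
drop is ≈ 2, not 1.

SHAP-style attributions are not implemented; `shap` can be applied
externally to the fitted `estimator` attribute of any trained model.

## Problem sizes

The test suite validates geometry against 10⁴-sample brute-force oracles and
runs the full default 19,200-frame study simulation for the end-to-end
properties (two-stage recovery, tree-vs-linear ordering, correlation signs);
unit tests use 2–4 subject reductions of the same generator. The acceptance
script re-runs the complete study-scale workflow in well under a minute on
one CPU.

## Known limitations

- Validated on synthetic landmarks only; the noise model is stylized.
- Right shoulder only; left-side features exist but no left-side target.
- Fixed standing posture, straight elbow, coronal-plane motion; no dynamic
  (time-series) smoothing.
- The camera model interpolates between trained yaws but extrapolates poorly
  outside [−30, 45]°.
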