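# Methods

## Problem and scope

`fatiguekin` implements a non-contact perceived-fatigue classification
pipeline for a cyclic whole-body abduction task recorded with a frontal
depth camera. The input is a 32-joint skeleton stream (Azure Kinect Body
Tracking joint set, positions in millimeters) plus a log of Borg CR10
exertion ratings reported every 30 s. The output is a three-class
(Low / Medium / High) fatigue label per movement window, evaluated with a
random forest under leave-one-subject-out cross-validation (LOSO) and
three class-imbalance strategies. Because no raw recordings ship with the
package, a synthetic cohort generator with analytic ground truth provides
the data; every stage is exercised against closed-form oracles.

## Synthetic movement model

Each simulated subject alternates between a neutral stance and a spread
(arms/legs abducted) posture. Per limb, the abduction angle is

    theta(t) = A(t) * (1 - cos phi(t)) / 2,    phi'(t) = 2*pi / T(t),

so theta oscillates between 0 ("close") and A(t) ("open"). Latent fatigue
F(t) = min(1, r·t/180) drives two drifts:

* period     T(t) = T0 · (1 + beta_T · F(t))   — movement slows;
* amplitude  A(t) = A0 · (1 − beta_A · F(t))   — movement shrinks.

CR10 reports at t = 30, 60, … s are `clip(round(10·F(t)) + jitter, 0, 10)`.
Joint positions come from planar forward kinematics in the frontal (x–y)
plane: shoulder/hip roots are fixed on a static pelvis-rooted torso, and
elbow/wrist (knee/ankle) are placed along the limb direction
(±sin θ, −cos θ). Remaining joints of the 32-joint set are static.
Sensor imperfections: isotropic Gaussian position noise (default SD 3 mm),
per-joint dropout runs (start probability 0.01/frame, run length ≤ 5
frames), and occasional ±1 CR10 report errors (probability 0.1).

Closed forms used as test oracles: instantaneous period T(t), amplitude
A(t), and peak opening velocity A(t)·π/T(t) (`analytic_truth`).

### Default cohort parameters

10 subjects, 180 s at 30 fps, per-subject draws (uniform):
T0 ∈ [1.9, 2.5] s, arm A0 ∈ [1.15, 1.4] rad, leg A0 ∈ [0.38, 0.52] rad,
beta_T ∈ [0.45, 0.65], beta_A ∈ [0.30, 0.45], r ∈ [1.0, 1.5].

These effect sizes are the package's own design choice, not measured
values: they were set once so that (a) every subject produces windows in
all three CR10 bands (r ≥ 1 reaches CR10 10 within the trial while the
first 30-s report is still in the Low band), (b) the cohort is imbalanced
toward High — subjects spend most of the trial fatigued — giving the
imbalance strategies something to correct, and (c) the fatigue drift is
large relative to the between-subject baseline spread, so classes are
separable across subjects under LOSO. Real cohorts differ in ways the
generator does not emulate: idiosyncratic movement style beyond a scalar
period/amplitude, non-monotone fatigue, correlated multi-joint noise, and
occlusion-structured (rather than independent) dropouts. Passing tests
therefore validate the pipeline's correctness and the direction of its
comparisons, not the study-level effect sizes.

## Feature extraction

1. **Units**: coordinates are divided by 1000 (mm → m) before any
   kinematics; the conversion refuses to run twice.
2. **Dropouts**: per-coordinate linear interpolation for missing runs of
   ≤ 10 frames (0.33 s at 30 fps); longer runs are bridged on the scalar
   angle series with a logged warning, since a window-level feature is
   robust to a brief bridge but a NaN would poison the whole trace. Edge
   gaps take the nearest valid value.
3. **Angle**: theta = atan2(|x_distal − x_proximal|, −(y_distal −
   y_proximal)) — the limb vector (shoulder→elbow, hip→knee) projected on
   the frontal plane against the downward vertical. The |x| makes left
   and right mirror-symmetric; the construction is invariant to limb
   length, translation and uniform scale. A full-3D variant
   (`angle_mode="3d"`) includes the depth axis.
4. **Smoothing**: Savitzky–Golay, window 15 frames (0.5 s), polyorder 3,
   applied to the angle series (configurable to raw positions). SG was
   chosen over a moving average because it attenuates the velocity peaks
   the features need by < 2 % at cycle periods ≥ 10 windows. Edges use
   the fitted edge polynomial, so constants and linear trends pass
   through unchanged.
5. **Differentiation**: central differences, one-sided at the edges.
6. **Cycle events**: "open" = local maxima with prominence ≥ 0.2 × the
   trace's angle range and ≥ 0.5 s separation; "close" analogous on the
   negated trace; alternation enforced by keeping the more extreme of
   consecutive same-kind events; plateau ties resolve to the earliest
   frame. Relative prominence keeps late (shrunken) cycles detectable.
   An angle range below 0.05 rad raises a no-movement error.
7. **Per-cycle features** (per limb, from the event pattern
   close–open–close–open): mean angle and peak angular velocity over the
   close→open phase, minimum angular velocity over open→close, the two
   phase durations, and the open→open inter-cycle interval.
8. **Windows**: non-overlapping groups of 3 consecutive cycles per limb,
   averaged; the limb with fewest cycles limits the window count and
   trailing remainders are dropped. 6 quantities × 4 limbs = 24 features
   (f01–f24; block order: mean angles, peak velocities, open times,
   minimum velocities, close times, inter-cycle intervals; limb order
   within a block: left leg, right leg, left arm, right arm).
9. **Labels**: a report at t_r owns the segment (t_r − 30, t_r]; a window
   takes the rating of the segment containing its midpoint (midpoint
   satisfies both the "preceding segment" and "nearest timestamp"
   readings for windows shorter than 30 s). Windows before the first
   segment take the first report; past the last, the last. Bands:
   Low = CR10 0–3, Medium = 4–6, High ≥ 7.

## Classification and evaluation

Random forest: 500 trees, sqrt feature subsampling, unlimited depth,
min_samples_leaf 1, random_state 42 (scikit-learn). LOSO: one fold per
subject; a shared subject between train and test raises a hard error.
Strategies, applied to training folds only:

* **none** — no correction;
* **class_weight** — w_c = N / (K·n_c) with K = 3, so every class carries
  equal weighted mass N/K (scikit-learn's "balanced" formula, computed
  in-package and passed as an explicit dict);
* **oversample** — uniform random duplication with replacement up to an
  exact 1:1:1 ratio at the fold's majority count, seed 42, all originals
  retained. No synthetic sample generation.

A training fold missing a class raises by default for the two corrective
strategies (the weight formula is undefined at n_c = 0);
`allow_missing_class=True` corrects over the present classes only.

Metrics are pooled LOSO point estimates (predictions concatenated across
folds, then scored once): per-subject folds can lack a class, which would
make per-fold macro metrics undefined. Macro one-vs-rest ROC AUC is
computed per class from the midrank Mann–Whitney U statistic (ties get
half credit), averaged unweighted over classes with at least one positive
and one negative; probabilities are the forest's mean per-tree leaf
frequencies. Impurity importances are normalized to sum to 1 within each
fold, then averaged across folds; segment importances sum each limb's six
features per fold, normalize to 100 %, and average. The limb grouping
(f01,f05,f09,f13,f17,f21 → left leg, etc.) is the only grouping the
feature table supports.

## Numerical conventions and degenerate inputs

* Event timing is quantized to the frame grid; timing assertions allow
  one frame (1/fps) of slack.
* Skeleton CSVs round-trip at 6 significant digits; empty cells encode
  missing joints.
* Probability simplices and importance sums are asserted to 1e−9;
  segment percentages to 1e−6.
* All randomness flows through `numpy.random.default_rng`; per-subject
  streams derive from (cohort seed, subject index) via `SeedSequence`, so
  cohorts are reproducible independent of generation order.
* Problem sizes in the shipped analysis: 10 subjects × 180 s × 30 fps
  (~54 k frames/subject), ~70 cycles/subject, ~200 windows/cohort —
  enough for stable LOSO folds while a full three-strategy evaluation
  completes in well under a minute.

## Known limitations

* The movement model is strictly frontal-plane and single-frequency; it
  cannot probe transverse/sagittal compensation strategies.
* CR10 coupling to latent fatigue is deterministic up to ±1 jitter; real
  perceived-exertion reporting is noisier and subject-specific.
* The vertical-reference abduction angle is one reading of "hip–knee
  opening angle"; a trunk-referenced variant is provided but untested
  against any external standard.
* Headline classification numbers on synthetic cohorts characterize the
  pipeline, not any human population.
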