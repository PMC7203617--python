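# Methods

## Synthetic sessions

The generator produces the statistical structure the analysis assumes,
with ground truth retained for testing.

**Cohort.** Each participant carries two latent per-frame propensities —
`latent_distraction` (probability of gazing at a distractor) and
`latent_offtask` (probability of being "nowhere in particular") — plus a
7x7 row-stochastic emotion-confusion profile. Group distraction
parameters default to the study's per-participant distraction-ratio
moments (ASD mean 0.0433, SD 0.0911; NC mean 0.0139, SD 0.0215) and are
drawn from moment-matched Beta distributions: bounded support, and the
method of moments stays valid even for the strongly skewed ASD group.
Infeasible mean/SD combinations (SD^2 >= mean(1-mean)) are rejected with
an error naming the group. Off-task propensities (defaults: ASD
0.10 +/- 0.05, NC 0.05 +/- 0.03) and confusion-profile diagonal
accuracies (ASD 0.65, NC 0.80) have no printed counterpart; they are
fixed at values that give plausible N-frame rates and response accuracy
for school-age children, and they matter only through the features they
feed. Ages are uniform on 6-17 (ASD) / 8-17 (NC) and gender follows the
reported 13/16 and 9/17 male fractions. Clinical scores (SCQ/SRS/ABIQ)
are generated as inert metadata in the reported ranges and are never used
by the analysis.

**Schedule.** Trials default to 41/42/41 stimuli of 6 s each (the
per-trial counts are treated as authoritative), emotions balanced within
trial up to remainder, feedback on trial 2 only, and a 5 s central
validation dot after every completed block of eight stimuli. The
eye-camera frame rate is not a protocol constant; the generator default
is 30 fps, and the analysis scripts and statistical experiments run at
5-10 fps, which leaves every estimator unbiased while keeping simulated
sessions small.

**Gaze.** Within each stimulus window the latent target follows a sticky
first-order Markov chain over {F, L, R, N} with kernel
`dwell * I + (1 - dwell) * 1 pi^T`, whose stationary distribution `pi`
puts mass `latent_distraction` on L+R (split evenly) and `latent_offtask`
on N. The chain restarts from `pi` at each stimulus onset, so
frame-fraction statistics are exactly unbiased for any dwell; dwell
defaults to 0.9, giving fixation runs of ~10 frames. Only frame fractions
have printed counterparts — the dwell parameter is a modeling choice that
controls autocorrelation (and hence the variance) of the ratios, not
their means. Emitted coordinates are the target-region center plus
isotropic Gaussian noise (default SD 0.01 normalized units); N frames
emit a uniform point outside all regions, or a missing value when
configured, since both occur in real recordings. Dot frames target the
screen center.

**Calibration truth and pupil streams.** A session is partitioned into
four epochs (dedicated calibration at the start and after each trial),
each with an affine pupil-to-world map: a shared near-identity base plus
a per-epoch drift offset, emulating headset slippage. Interior epoch
boundaries are snapped to validation-dot midpoints — switches coincide
with recalibrations in the protocol — which also makes the noiseless
round trip exact (see below). Affine truth keeps the inverse closed-form
for pupil synthesis; the degree-2 fitting default recovers it with ~1e-16
residual, and quadratic recovery is tested on directly constructed
quadratic pairs. The generator also emits per-epoch calibration-point
pairs (a 3x3 grid of screen targets with their pupil projections), which
is what the calibration stage fits on.

**Rendering.** Eye frames are a bright field with a soft-edged dark disk
of configurable radius at the scaled pupil coordinate plus additive
Gaussian noise; ground-truth centers are returned alongside. No glints,
eyelids, or 3-D eyeball geometry are modeled.

What the generator does *not* emulate: real pupil-image texture, blinks
and partial occlusions, smooth pursuit, head slippage within an epoch,
systematic (non-Gaussian) calibration error, or response omissions.
Passing tests therefore demonstrate correctness of the computations and
recoverability under the stated noise model — not robustness to real
recording pathology.

## Pupil detection

- **MSER** is implemented as a threshold sweep over the dark component
  tree: 24 levels, region stability scored by relative area growth across
  +/-2 levels, area gate 0.5-20% of the image, eccentricity gate 0.95,
  candidates ranked most-stable-first with proximity deduplication.
- **Gradient** follows the means-of-gradients objective: the center
  maximizes the mean squared positive alignment between displacement
  directions and image gradients, weighted by inverted smoothed intensity
  at the candidate. Gradients are taken on a sigma = 2.5 smoothed image
  and restricted to the top 5% of gradient magnitudes; the objective is
  evaluated on a stride-2 grid, refined at full resolution, and finished
  with quadratic sub-pixel interpolation. The heavier smoothing trades a
  few hundredths of a pixel of noiseless accuracy for stability under
  image noise, keeping the detector competitive with the
  (area-averaging, hence noise-robust) MSER centroid.
- **Flow** translates the previous center by a windowed (24 px) phase
  correlation shift with 0.1 px upsampling; confidence decays with the
  registration error. It is a propagation method: useful for smooth
  motion and as a last resort, poor under large jumps.
- **Fusion**: if the gradient estimate agrees with an MSER candidate
  within a 4 px gate, their average is returned (method `fused`);
  otherwise the highest-confidence non-flow candidate; otherwise the flow
  propagation; otherwise the frame is marked untrackable. The combination
  rule is this package's own design — simple, testable, and degrading
  gracefully — and the averaging branch is what lets the hybrid beat each
  single method on noisy frames.

## Calibration and epoch assignment

Each epoch model is a per-axis least-squares fit over the full bivariate
monomial basis up to total degree 2 (configurable 1-3; degree 2 is the
standard choice for monocular 2-D regression calibration). Rank-deficient
designs (e.g. collinear pupil points) are rejected with a named error.
The protocol's human "visual inspection" that matched session intervals
to candidate models is replaced by a deterministic rule: segments are
delimited by dot midpoints, each segment is scored per model by the
median prediction error against the central dot target over the dot
frames it contains, and the best model wins unless its error exceeds a
geometry-derived threshold (half the face half-width, 0.1225 — an
assignment worse than that cannot separate face from distractor), in
which case the segment is assigned to no model and its frames are dropped
from coding. With no dots at all, the lowest-fit-residual model is
assigned with a warning.

## Coding and distraction statistics

Frames are coded by boundary-inclusive rectangle membership (any fixed
convention works; inclusivity avoids zero-measure gaps), with missing and
off-screen points coded N. Regions are vertically centered, distractors
horizontally centered in the strips beside the face — sizes are printed
in the protocol, positions are not. Whole participant-trials whose
trackable-frame fraction falls below 0.5 are excluded (the study's
exclusion criteria are not public; this surrogate is explicit,
configurable, and logged). `d = (L+R)/(F+L+R+N)` includes N in the
denominator; `d_FLR` excludes it, hence `d <= d_FLR` wherever the latter
is defined. d(p) averages all valid stimulus windows with equal weight
(equal-trial weighting is the logged alternative when exclusions
unbalance trials). The primary test is one-tailed Welch (the groups'
variances differ several-fold); pooled-variance is available by flag. The
degenerate zero-variance/equal-means case returns p = 0.5, flagged.

## Features and classification

Per trial: cm 49 + conf S + gaze 3S + pat 2 = 4S + 51 (219 at S = 42).
Gaze features: face fraction excludes N from the denominator (face
versus "either of the distractors"); "changes of gaze fixations toward
the face" is read literally as distinct-code transitions with destination
F over all distinct-code transitions (N-involving transitions included);
latency is the first F frame index, or the window length when the face is
never fixated. Undefined cells (no retained frames, no transitions) stay
NaN in the table and are imputed with training-fold column medians inside
each cross-validation fold — fold-internal imputation and
standardization avoid information leakage. Gender is coded male = 0
(arbitrary but fixed; penalized linear models are insensitive to the
polarity after standardization). In concatenated tables `pat` appears
once — duplicated copies are degenerate under standardization.

The elastic net is logistic loss with a combined l1+l2 penalty
(scikit-learn saga); a least-squares elastic net thresholded at 0.5 is
available as `loss="linear"`, and its ridge special case (l1 mixing 0)
has a closed-form solver (dual form when features outnumber
participants) that makes permutation experiments cheap. Hyperparameters
are selected by accuracy-maximizing stratified inner CV (up to 5 folds)
on each LOPO training fold; single-point grids skip the inner loop.
Predicted probability exactly 0.5 maps to NC, a fixed logged convention.
Shuffle tests permute labels at the participant level — the exchangeable
unit under LOPO — and report the add-one p-value, which is never zero,
plus a convergence flag (running p within +/-0.01 of the final value over
the last half of iterations). The ablation grid covers all 15 non-empty
family subsets by 4 trial selections.

## Problem sizes in tests and the acceptance script

Statistical checks use scaled study conditions chosen to keep estimators
unbiased: cohorts are always 16 + 17 with the printed distraction
moments; gaze simulations run at 5-10 fps (frame rate affects only the
per-window frame count); parameter-recovery tolerances are 3 standard
errors over 200 seeded replicates; shuffle-test calibration uses B = 199
permutations and 200 replicates against the exact binomial 99% interval;
the planted-signal ranking check uses 20 replicates with group signal
placed only in gaze behavior (distraction means 0.25 vs 0.05, identical
confusion profiles), decided before any runs. The pupil benchmark uses
500 rendered frames at 10% noise with fixed seeds.

## Known limitations

- The fusion rule, epoch-assignment rule, and outlier criteria stand in
  for semi-manual steps whose exact protocols are not public; they are
  declared designs, not inferences.
- MSER stability uses a fixed-level sweep rather than a full component
  tree; adequate for disk-like pupils, not a general MSER.
- The flow detector assumes small inter-frame motion; on the synthetic
  streams used here (independent per-frame positions) it mainly exercises
  the fallback logic.
- Group confusion structure is uniform off-diagonal; real emotion
  confusions are patterned (e.g. fear/surprise), which would mostly make
  cm features more informative than they are here.
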