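# Methods

`coilpose` estimates the 2D centerline ("pose") of a single *C. elegans*
from grayscale video frames, including the coiled and self-occluded
postures where classical skeletonization fails. This note records the
models, the numerical choices, and what the synthetic test bed does and
does not establish.

## Pose representation

A pose is the vector of tangent angles `theta = (theta_1 … theta_N)` of N
equal-length centerline segments ordered head to tail (N = 100, giving 101
skeleton points). Skeleton coordinates follow from cumulative summation,
`P_{i+1} = P_i + dS (cos theta_i, sin theta_i)`, with `dS` the segment
length in pixels; the inverse is `atan2` of segment differences. Image
coordinates are x = column, y = row with y increasing downward, and all
angle arithmetic is wrapped into `(-pi, pi]` through
`eps(a, b) = atan2(sin(a-b), cos(a-b))`.

A single image cannot always distinguish head from tail, so the pose
`theta` and its reversal `flip(theta) = reverse(theta) + pi` are treated as
equivalent throughout: the training loss, the prediction API and the
evaluation all operate on unoriented poses, and orientation is recovered
afterwards from temporal continuity plus the sparse head-tail labels that
classical trackers provide.

For linear ("eigenworm") analysis the wrapped angle vector of a deep coil
is misleading — the smooth tangent curve exceeds ±pi and wrapping inserts
2-pi jumps — so mode projections always unwrap along the body first
(`numpy.unwrap` over the angle index). Projections use components that are
orthogonal to the constant vector, making them invariant to global body
rotation.

## Generative shape model

Posture variability is modeled by a Gaussian mixture with full covariances
over angle vectors, fitted by EM (scikit-learn's `GaussianMixture` stands
behind the module surface). Defaults: `reg_covar = 1e-6` on the diagonal
(100-dimensional data with few points per component is otherwise
singular), k-means initialization, one initialization, 100 iterations,
tolerance 1e-3, all seed-controlled. The number of components defaults to
270 — appropriate for a library of ~15000 shapes — and is selected in
practice by the AIC curve (`2k − 2 log L`); smaller libraries use
proportionally fewer components. Training libraries should balance coiled
against uncoiled postures; `balance_by_curvature` implements
inverse-frequency resampling over a 30-bin histogram of the turning mode
a3, with replacement so sparse deep-coil bins are re-used rather than
exhausted. The GMM is fitted on body-unwrapped angle vectors for the same
reason projections unwrap; samples are wrapped into `(-pi, pi]` on the way
out, which is immaterial to rendering (only cos/sin are used) and to the
training loss (which wraps differences).

## Frame standardization

Segmentation: Gaussian blur (5 px window), automatic Otsu threshold with
the minority class taken as foreground, morphological closing (3x3, one
iteration), 8-connected components, and selection of the largest blob
overlapping the central region (the frame cropped 15 % per side for the
selection only). The background value is the mean of non-foreground pixels
of the original image. Frames are then cropped or padded to a square of
side L with the worm bounding box centered and every non-worm pixel set to
the background value. L defaults to the average length of the biggest worm
in the dataset and may not go below 32 px; color input is converted by
luminance.

## Synthetic image rendering ("reverse skeletonization")

Given a labeled reference frame (image, skeleton of N_S points, widths at
head/midbody/tail) and a target pose, the renderer:

1. builds the target skeleton with `dS = reference length / (N_S − 1)`,
   resampled by arc length to N_S points and centered in the canvas;
2. interpolates per-point widths from the three labeled widths with
   landmark fractions (0.15, 0.5, 0.85) of arc length — constant beyond
   the head/tail landmarks, linear between;
3. warps a rectangular texture patch starting at **every** skeleton index
   (length `step = N_S/16` segments, width `1.2 × local width`) from the
   reference onto the target. Because source and target patches are true
   rectangles, the three-corner affine map is evaluated in closed form
   through the rectangles' local coordinates, with bilinear sampling.
   Patches are drawn tail-first and alpha-blended: a new patch replaces
   uncovered pixels and averages (weight 0.5) with covered ones, so the
   head-end texture lands on top;
4. masks protrusions with a drawn body outline (per-segment quadrilaterals
   plus end caps), median-filters (window 3), and sets all non-worm pixels
   to the reference background.

Augmentations (per sample, seeded): translation up to ±5 % of the image
side, length 90–110 %, thickness multiplier 1.1–1.3, draw-order flip with
p = 0.5, and with p = 0.25 an extra Gaussian blur whose kernel is 3–10 %
of the image side capped at 13 px. Training poses add a global rotation
uniform on (0, 2pi] and a random head assignment; the reference pool is
capped at 1000 frames per process.

## Network and loss

The regressor is a pre-activation residual network: a 7x7/stride-2 stem
convolution, 2x2 max pooling, three stages of basic blocks
(BN → LeakyReLU(0.1) → conv3x3 → BN → LeakyReLU → conv3x3 plus identity or
1x1-projection shortcut), then global average pooling and a dense layer of
100 outputs. The full-scale configuration uses 3 blocks per stage with
(32, 64, 128) filters at 128 px input; the *reduced* configuration used by
all desk-scale experiments is 2 blocks per stage with (16, 32, 64) filters
at 48 px (~180k parameters). Inputs are scaled to [0, 1] with the
per-image background mean subtracted; outputs are raw angle values (no
activation), safe because the loss wraps differences.

The loss is head-tail symmetric: `min(d(theta_hat, theta_a),
d(theta_hat, flip(theta_a)))` with `d` the RMS wrapped angle distance.
Only the winning branch receives gradient; the gradient of the wrapped
difference is taken as the wrapped difference itself (an identity almost
everywhere). Exact invariance to flipping either argument is tested.

All layers — im2col convolutions, batch normalization (momentum 0.9,
eps 1e-5, standard moving-average statistics also for small datasets),
pooling, Adam — are implemented directly on NumPy arrays with hand-derived
backpropagation, verified against finite differences. Training is
deterministic given the seed. Optimization follows the full-scale recipe
(Adam, learning rate 1e-3, batch 128, best-evaluation-loss checkpointing);
`TrainConfig.learning_rates` optionally sets a per-epoch schedule, and the
short desk-scale runs decay 1e-3 → 3e-4 → 1e-4 over the final quarter of
epochs — a refinement the 100-epoch recipe does not need (probed: ~12 %
lower evaluation loss at matched wall-clock).

## Post-prediction

*Image error.* Each predicted pose is rendered from the nearest labeled
reference, cropped to the worm bounding box plus 2 px, and slid over the
input frame computing the normalized correlation coefficient; the error is
`1 − |c|_max` (absolute value, so reversed-intensity imaging still scores
0) and the argmax locates the skeleton. Frames above a threshold (default
0.3, chosen from the error distribution on trusted labeled frames) are
discarded.

*Head-tail resolution.* A greedy pass builds segments of temporally
consistent poses: each frame takes the orientation minimizing the mean
absolute angle distance to the last aligned frame; above 30° the frame
becomes a gap, and if nothing rejoins within 0.2 s a new segment starts
(random initial orientation, seeded). Segments shorter than 0.2 s are
discarded; exact orientation ties keep the incumbent. Whole segments are
then flipped to maximize cosine similarity between predicted and labeled
head-to-tail vectors (first to last skeleton point); unlabeled segments
inherit orientation from the nearest aligned neighbor via their two
closest frames, iterated to a fixed point; the remainder is flagged.

*Interpolation and smoothing* (optional): gaps of ≤ 4 frames are filled
per angle index by third-order splines over up to four valid frames on
each side (angles unwrapped in time first); longer gaps are left. The
angle series is smoothed with a Savitzky-Golay filter, order 3. The
nominal 8-frame window is realized as a centered window of 9 because the
filter needs symmetric support; this is recorded in the configuration.

## Behavior analysis

Centroid series are downsampled to 3 Hz; velocity is the finite difference
(dt = 1/3 s), speed its norm, and angular speed the angle between
successive displacement vectors divided by dt. Non-overlapping 10 s boxcar
means of speed and angular speed feed a two-state Gaussian HMM (diagonal
covariance, Baum-Welch via hmmlearn, Viterbi decoding, seed-controlled).
States are canonically labeled: roaming is the state with the larger mean
speed. Movement direction is `delta_psi = atan2(v_y, v_x) − mean(theta)`,
normalized into `[-pi/2, 3pi/2)`; forward means `delta_psi < pi/2`. The
body-wave phase is `phi = atan2(a2, a1)` — the quadrant-correct angle, a
deliberate reading of the inverse-tangent notation since the phase winds
through all quadrants; the opposite sign convention is available as a flag
and only flips the forward/backward labeling of the phase velocity
`omega = d phi/dt` (cubic-spline derivative). Complete body waves are
counted as peaks of cos(phi) with prominence 1.95 and minimum separation
8 frames inside maximal constant-sign runs of omega. Turning statistics
report the per-state distribution of a3 with the Omega-turn band
(10 ≤ |a3| < 20) and delta-turn band (|a3| ≥ 20); bands use |a3| because
the sign of a computed eigenbasis component is conventional.

## The synthetic test bed

`fixtures.generate_fixture_video` renders a procedural worm so every stage
is testable without recordings: tangent angles are driven through a
constructed orthonormal basis (a quadrature sinusoid pair of 1.5
body-wavelengths for the traveling wave, a centered ramp for turning, two
small harmonics), with amplitude ~5.5 eigen units (tangent amplitude
~0.8 rad), wave frequency 0.5 Hz, a slow orientation random walk, and
raised-cosine deep-turn bouts reaching |a3| ≈ 24 every ~8 s. The body is a
40 px worm (widths 4/8/4 px) drawn dark on a light background with an
interior depth profile, 0.5 px blur and sigma = 3 pixel noise at 30 Hz.
The generator also emits the photometric ground-truth body mask (the
half-contrast contour of the noiseless image) and marks frames with
|a3| < 10 as "labeled", mimicking classical-tracker coverage.

The fixture's shape library (`fixture_shape_corpus`) mixes equal
populations of uncoiled shapes and coils uniform in |a3| up to 24, in the
body frame. The evaluation eigenbasis is computed by PCA on the *uncoiled*
part of the library (selected by the linear-trend coefficient of the angle
profile, threshold 10) so that the wave pair ranks first and the turning
mode third, matching eigenworm convention; a curvature-balanced ensemble
would rank the turning mode first.

What passing on fixtures shows: the renderer, loss, optimization, scoring,
orientation logic and behavioral statistics work end to end, and the
network can learn pose from images whose texture statistics it has seen.
What it does not show: robustness to real-world texture diversity
(lighting gradients, debris, translucency), to tracker labeling errors, or
to body shapes outside the generative model — those require real
recordings and the full-scale training recipe.

## Desk-scale accuracy experiment

`evaluation.mode_error_experiment` is the package's headline measurement,
sized for a single CPU (`scripts/acceptance.py` runs it): 60 procedural
references at 48 px (N_S = 33), a 40-component GMM on a 4000-shape
library, 24000 rendered training images, the reduced network trained 16
epochs (batch 128, the decaying schedule above, checkpoint on a 300-image
held-out rendering), and 2000 held-out synthetic evaluation images. For
each evaluation image the predicted and true centerlines are body-unwrapped
and projected onto the fixture eigenbasis; the per-image mode error takes
the minimum over the two head-tail orientations, and medians are reported
overall and for the coiled subset (|a3| > 15, ~28 % of draws). The
experiment runs in roughly a quarter hour; at this budget the regressor
remains under-trained relative to the full-scale recipe (two orders of
magnitude fewer gradient steps), which bounds the attainable mode errors —
the limitation is optimization time, not the method.

## Pipeline and formats

`run_pipeline` chains preprocessing, reference building, shape-model fit
(or load), rendering, training (or a supplied checkpoint), prediction,
scoring, orientation, interpolation/smoothing and optional behavior
analysis, caching every stage under a run directory with a manifest
(config, seeds, timings) so runs resume and reproduce bit-identically.
Data enters only through the `DatasetAdapter` API (indexed frames, labeled
features, segmentation hook); adapters register programmatically or via
`coilpose.adapters` entry points. Results export to WCON (JSON) with t/x/y
per skeleton point, head at the first point. Model checkpoints store an
architecture JSON plus weight arrays; the shape model serializes to a
versioned `.npz`.
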