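# Methods notes

This note documents the models, numerical choices and known limitations of
`posmov`, in the spirit of a package methods appendix. It states no
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

A reference recording consists of four limb-worn IMU sensors (left/right
arm, left/right leg), each streaming triaxial acceleration (m/s², ±8 g) and
angular velocity (deg/s, ±500 deg/s) at 52 Hz on a shared uniform time
base. Human annotators label three parallel interval tracks from
synchronized video: posture (7 categories: prone, supine, side left/right,
crawl, sitting, standing), movement (9 categories: still, proto,
elementary, fluent, transition, roll left/right, pivot left/right) and
auxiliary (carried / out of camera; such frames are excluded from training
and evaluation). A *recording configuration* is a triple (sensor placement
subset, modality variant, sampling frequency); the pipeline quantifies how
classification and its recording-level derivatives degrade as the
configuration is reduced.

## Synthetic cohorts

The generator emulates the statistical structure the analysis depends on,
not infant biomechanics.

**Behavior.** Posture is a semi-Markov chain: bout durations are shifted
log-normals `1 s + LogNormal(ln 8 s, 0.5)` (median 9 s, within the 8–20 s
range typical of annotated posture bouts; the moderate dispersion keeps a
single long bout from dominating a short session, which matters for the
stability of recording-level occupancy estimates). The successor posture is
drawn from the age-interpolated occupancy profile (excluding the current
posture), so long-run occupancy tracks the profile. Occupancy interpolates
linearly in age between a "young" profile (supine+prone ≈ 68 % at 4.5
months) and an "old" profile (crawl+sitting+standing ≈ 88 % at 16.6
months). Cohort ages are sampled stratified — one uniform draw per
equal-width age bin, then shuffled — emulating cross-sectional recruitment
that deliberately covers the studied age range (4.5–16.6 months).
Within each posture bout, movements form a nested semi-Markov
chain restricted to the posture's sensible movements, with durations
`1 s + LogNormal(ln 2.5 s, 0.8)`; a trailing fragment shorter than 1 s is
absorbed into the final bout. These constants realize the qualitative
duration structure of naturalistic annotation: essentially no bouts under
1 s, and roughly 10–40 % of movement bouts under 2 s while posture bouts
run an order of magnitude longer. Movement propensities also shift with age
(proto declines, fluent rises), which — together with the occupancy shift —
is what makes age recoverable from distribution features (BIMS).

**Signals.** Each sensor sees gravity (9.81 m/s²) along a posture-specific
unit direction, smoothed through transitions with a 0.5 s crossfade, plus
band-limited (1–10 Hz) noise whose RMS is set by the movement category, plus
white sensor noise. Gyroscopes carry a constant per-channel bias
(σ = 2 deg/s), category-dependent band noise, and *signed* low-frequency
rate components for rolls (±x) and pivots (±z) — so the gyroscope carries
movement-direction information that accelerometers lack, mirroring the
modality gap seen on real data. Two emulation choices are deliberate and
should not be read as findings: (a) arm sensors get slowly wandering
orientations, extra category-independent motor noise, and gravity maps that
are nearly degenerate across the lying postures, while (b) leg gravity maps
are distinct for lying/standing but nearly degenerate for crawl vs sitting
(which the arm maps resolve). Arms and legs are therefore complementary,
legs are individually more informative than arms, and the placement
hierarchy observed on real data (2Arm2Leg > … > 1Arm) becomes recoverable
by construction.

**Annotators.** Each simulated annotator re-labels the true tracks through
(i) Gaussian boundary jitter (σ = 0.25 s posture, 0.45 s movement) and
(ii) segment-level category confusion (rates 0.013 posture, 0.12 movement)
drawn from structured kernels (e.g. prone→crawl, still→proto). The
auxiliary track (default 10 % of the session) is shared across annotators,
as it reflects the video rather than judgement. The jitter/confusion
defaults were calibrated once so that a default cohort reproduces pairwise
inter-rater kappa ≈ 0.93 (posture) and ≈ 0.59 (movement); the movement
track's lower agreement emerges mostly from jitter interacting with short
bouts, as it should.

**What the generator does not model:** carrying-detection errors (the mask
is generated, not inferred), limb-to-limb kinematic coupling, repetitive
rhythmic movement, sensor detachment, and real annotator idiosyncrasies.
Passing tests therefore demonstrate that the *pipeline* recovers structure
the generator encodes — not classifier performance on real infants.

## Configuration reduction

All reduced sampling rates are *simulated on the 52 Hz grid* so that every
classifier variant consumes identical 120-sample (2.3 s) frames with 60
sample (50 %) hop: anti-alias zero-phase 6th-order Butterworth low-pass at
half the decimated rate, sample dropping, Fourier-method upsampling back to
the original grid, and the same zero-phase low-pass once more. The
anti-alias pass and the Fourier upsampling are the two numerically open
choices: without the former, out-of-band energy aliases into the passband
and corrupts the rate-reduction comparison; polynomial interpolation in
place of the latter attenuates in-band content by several percent (linear
interpolation ≈ 7 % at 2 Hz for the 13 Hz variant) and breaks the
idempotence of the operation. Nominal 6 Hz and 3 Hz rates are realized by
the nearest integer decimation factors (8 → 6.5 Hz, 16 → 3.25 Hz).

The pre-processed accelerometer modality splits acceleration with a
zero-phase 8th-order Butterworth low-pass at 0.5 Hz; the high-pass part is
defined as the subtraction residual, making `low + high == raw` an exact
identity. Gyro bias is estimated as the per-channel whole-recording median
(robust to movement bouts; the estimation method is otherwise
unconstrained). Stream layout per modality: raw accelerometer → 1 stream;
pre-processed → 2 streams (low, high); acc+gyro → 3 streams (low, high,
de-biased gyro), channels concatenated across sensors within each stream.

Frame labels: per annotator, each frame takes the category with the largest
temporal overlap with its 2.3 s window (ties to the lower category index);
the training target is the majority vote across annotators with ties
resolved to the first annotator. Any overlap with an auxiliary segment
masks the frame on all tracks. The majority vote replaces an iterative
annotation-refinement procedure whose details are external to this
pipeline.

## Classifier

One input head per stream: 3 convolution layers (kernel 5, stride 2) over
the 120-sample axis, ReLU, mean-pooled to a head embedding; embeddings are
concatenated and projected to the frame latent (160-dim at reference
scale). The temporal module stacks residual blocks of symmetric
(non-causal) dilated convolutions over the frame axis — kernel 3, dilations
(1, 2, 4, 8), each block `x + conv1×1(relu(conv_dilated(x)))` — for a
receptive field of 31 frames (±15 frames ≈ 34.6 s), then a 1×1 output
convolution per track. Only the latent size and the ~30-frame receptive
field are externally constrained; head widths, block counts and kernel
sizes are this package's realization, scalable via `ModelSpec`. Inputs are
scaled inside the model (accelerometer streams by 1/9.81, gyro by 1/100) so
optimization is well conditioned while the preprocessing streams keep
physical units.

The network is implemented in numpy with hand-written backprop (im2col
convolutions, Adam). Training follows the reference protocol:
recording-level k-fold cross-validation with a fixed seed, 20 % of training
recordings held out for validation, batches of 100 consecutive frames,
categorical cross-entropy weighted by inverse class priors of the training
split (classes absent from a fold get weight 0 with a warning), and
augmentation with per-sequence probabilities 0.3 each: sensor dropout
(never the only sensor), sample dropout (independent zeroing at rate 0.3),
and one random Euler rotation (each angle uniform in ±15°) applied to every
acc/gyro 3-vector. "Sample dropout" is interpreted as independent
per-sample zeroing; no finer definition is available. Reference protocol:
learning rate 1e-4, 200 epochs, 10 folds. The **desk-scale** protocol used
by the tests (the study conditions of this package) is: reduced widths
(head 8, latent 16, temporal 16 — same dilation stack, so receptive-field
properties are preserved), 3 folds, 20–25 epochs, learning rate 3e-3 to
compensate for the small epoch budget, cohorts of 6–12 recordings of 3–10
minutes. Model selection is by validation Cohen kappa per epoch.

## Metrics and statistics

Performance is computed from a compound confusion matrix — every individual
annotation compared against the classifier output (or annotators against
each other in all pair combinations for inter-rater agreement), summed over
recordings — and reported as multiclass Cohen kappa computed from observed
vs marginal-implied chance agreement; on 2×2 matrices this equals the
closed form `k = 2(tp·tn − fn·fp)/((tp+fp)(fp+tn) + (tp+fn)(fn+tn))`
exactly. Degenerate marginals yield an undefined marker (NaN), never a
number. Confidence intervals use recording-level percentile bootstrap
(10,000 iterations at reference scale; compound statistics are recompounded
per resample). Configuration contrasts use two-tailed paired t tests on
systems matched on the other attributes, with a one-sample KS pre-check on
mean/σ-standardized differences against the standard normal; the
estimated-parameter bias of that pre-check is accepted. Both printed
significance legends are supported (figure legend .05/.005/.001 is the
default; methods legend .05/.001/.0001 by name).

## Aggregates and BIMS

Recording-level distributions are means of the carrying-mask-filtered
one-hot matrices along the frame axis. The posture-conditioned movement
representation uses a 7×9 sensibility matrix with exactly 27 admissible
pairs (rolls only from lying postures, pivots only in prone, fluent only in
crawl/sitting/standing, still everywhere, transition/proto/elementary over
the floor-based repertoire); the exact membership is this package's default
— consistent with the generator's constraint set — and is user-overridable.
Frames whose predicted pair is non-sensible are dropped and the
distribution renormalized over the sensible mass (the alternative,
remapping them to a nearest sensible pair, is not attempted). BIMS is the
Gaussian-process (constant × RBF + white kernel, marginal-likelihood
hyperparameters) expected age given the 34-dim feature vector (7 posture +
27 conditioned shares), mapped linearly from the training age span onto
[0, 100] and clamped. The kernel's length-scale and noise-level lower
bounds (0.2 and 0.5) keep the marginal-likelihood optimum away from the
interpolation collapse — a near-zero length scale with near-zero noise fits
the training set exactly and predicts the prior mean everywhere else —
which otherwise occurs regularly at the small training sizes (≈ 10
recordings per fold) the desk-scale protocol uses. Evaluation is recording-level cross-validated: the GP
is always fitted on annotation-derived reference features, and a
recording's own score (whether from reference or classifier-derived
features) comes from a fold model not trained on it.

## Degenerate inputs and tie-breaks

- Empty/fully-masked recordings yield undefined markers (None/NaN), not
  numbers, at every aggregation step.
- Frame-label ties break to the lower category index (per annotator) and to
  the first annotator (majority vote).
- Recordings shorter than one 120-sample window produce an empty frame
  tensor with a warning.
- Decimation factors must be positive integers; signals shorter than the
  filter warm-up are reflection-padded (`sosfiltfilt`).
- The fold assignment is a deterministic function of the training seed;
  identical seeds reproduce identical out-of-fold predictions exactly.

## Known limitations

- Desk-scale kappas are not comparable to values obtained on real infant
  data; only orderings and qualitative gaps are meaningful, which is why
  the end-to-end checks assert hierarchy (Spearman rank agreement, paired
  orderings) rather than absolute levels.
- The numpy network trains ~10² times slower per parameter than a GPU
  framework; the reference scale (160-dim latent, 200 epochs, 72-config
  grid) is available behind `ModelSpec.reference()` and `TrainingConfig()`
  but is not exercised by the tests.
- The Fourier upsampling step assumes quasi-stationary content near the
  signal edges; the zero-phase filters dominate edge behavior in practice.
- Bootstrap CIs are percentile, not BCa; with few recordings (< 10) they
  undercover slightly.
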