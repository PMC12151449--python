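# posmov

**Trade-offs between IMU recording configurations and the attainability of
posture/movement analyses**, as a tested, reusable Python pipeline.

Wearable inertial measurement units (IMUs) are the workhorse of real-world
human movement research. For infant gross-motor assessment, a multi-sensor
suit with four limb-worn IMUs (triaxial accelerometer + gyroscope, 52 Hz)
supports second-by-second classification of 7 postures and 9 movement
categories at human-equivalent agreement. But every simplification of the
recording setup — fewer sensors, accelerometer only, lower sampling rate —
trades away analytic power somewhere: at the frame level, in recording-level
category distributions, or in derived motor-maturity scores. `posmov`
implements the full machinery needed to quantify those trade-offs
systematically, and — because multi-sensor infant recordings are not openly
available — ships a first-class synthetic-data generator with known ground
truth so that every stage is testable end-to-end.

## What is inside

- **`posmov.synth`** — semi-Markov behavior simulator (age-dependent posture
  occupancy, posture-conditioned movements, realistic bout-duration
  structure), four-limb IMU signal synthesis (posture-specific gravity
  directions, movement-dependent band energies, gyro bias, signed roll/pivot
  signatures), and a calibrated multi-annotator error model (inter-rater
  kappa ≈ 0.93 posture / 0.59 movement).
- **`posmov.preprocess`** — configuration reduction: sensor-placement
  subsetting (8 variants from 2Arm2Leg down to 1Arm), sampling-rate
  simulation on the 52 Hz grid (zero-phase 6th-order Butterworth
  decimate/upsample chain), gravity/movement accelerometer split (zero-phase
  8th-order Butterworth, 0.5 Hz, exact additive identity), gyro bias
  removal, 2.3 s / 50 %-overlap framing, and overlap-based frame labeling
  with auxiliary-segment masking.
- **`posmov.classifier`** — the encoder + dilated temporal-convolution frame
  classifier (per-stream input heads, 160-dim latent and ~30-frame receptive
  field at reference scale), implemented in numpy with hand-written
  backprop, trained with Adam on inverse-prior-weighted cross-entropy,
  sensor/sample-dropout and rotation augmentation, and recording-level
  k-fold cross-validation with validation-kappa model selection.
- **`posmov.agreement`** — compound confusion matrices, multiclass Cohen
  kappa (equal to the printed 2×2 closed form on binary problems),
  recording-level percentile bootstrap CIs, paired t tests with a KS
  Gaussianity pre-check, Pearson r.
- **`posmov.aggregates`** — carrying-filtered category distributions, the
  27-combination posture-conditioned movement representation, and the BIMS
  motor-maturity score (Gaussian-process expected age, normalized to
  [0, 100]).
- **`posmov.experiment`** — the configuration grid (8 placements × 3 rates ×
  3 modalities = 72 systems at reference scale, desk-scale subsets in
  minutes), matched paired-t comparisons, extreme-decimation study, data-rate
  arithmetic, markdown reports.

## Worked example

```bash
python examples/04_interrater_agreement.py
```

```
posture   inter-rater kappa = 0.935
movement  inter-rater kappa = 0.585
```

The simulated annotators disagree through boundary jitter and
category confusion; posture (long, well-defined bouts) reaches kappa ≈ 0.94
while movement (median bout ≈ 3.5 s, ~20 % of bouts under 2 s) lands near
0.59 — the gap that makes frame-level movement metrics look pessimistic and
motivates recording-level aggregate statistics. The other examples generate
cohorts (`01`), reduce configurations (`02`), train and evaluate the
classifier (`03`), compute BIMS scores (`05`), and print configuration data
rates (`06` — the reference 4-sensor acc+gyro 52 Hz stream is 1248
numbers/s ≈ 5.0 kB/s; the minimal 2-sensor acc-only 13 Hz variant is 78
numbers/s, a 16× compression).

## Layout

```
src/posmov/        library (io, synth, preprocess, nn, classifier,
                   agreement, aggregates, experiment, vocab)
examples/          narrative scripts, one per capability
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py (calibration quantities, JSON output)
docs/methods.md    model and design notes
```
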