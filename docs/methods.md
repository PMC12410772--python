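# Methods

## Problem and pipeline

The package estimates the anterior-posterior ground reaction force
(AP-GRF) of a runner — its negative lobe is braking, its positive lobe
propulsion — from body-worn inertial sensors.  The pipeline is:

1. **Conditioning** (`signal_prep`): all IMU channels are low-pass
   filtered with a zero-phase (forward-backward) fourth-order Butterworth
   filter, cutoff 50 Hz.  Force-plate channels, sampled at 2 kHz in a lab
   setting, are filtered at 50 Hz and resampled onto the 120 Hz IMU frame
   grid, then divided by body weight (in N; g = 9.80665 m/s² when a mass
   is supplied) and expressed in %BW.
2. **Segmentation** (`gait segmentation`): training stances are maximal
   runs of vertical force above 20 N (initial contact = run start, toe
   off = first frame after).  Each stance window is extended by 29 frames
   (0.242 s, about the shortest swing phase) on each side so that models
   see swing context and can be applied to continuous recordings; windows
   clipped by the series bounds are flagged and excluded from training.
3. **Sub-sequences**: inputs are 22-frame slices (hop 1) of the
   normalized channels; the regression target is the AP-GRF at the slice
   mid-point, taken as 0-based index 11 of the even-length window.
   Continuous waveforms are re-assembled by placing each prediction at
   its mid-point frame; the leading 11 and trailing 10 frames of a series
   are NaN-marked as uncovered.
4. **Regressor** (`grf_model` / `nn`): two bidirectional LSTM layers of
   64 units, dropout 0.2 on the mid-point read-out, dense layers of 128
   and 64 units with ReLU, scalar output.  Smooth-L1 loss (β = 1), AdamW
   (lr 0.001, weight decay 0.01).  The network, backpropagation and
   optimizer are implemented in numpy/float32; training is deterministic
   given the seed.
5. **Inference segmentation**: on force-free recordings, swing phases are
   detected from the predictions themselves — at least five consecutive
   frames with magnitude ≤ 0.5 %BW and slope ≤ 0.25 %BW per frame; a
   run's first frame is TO, the frame after its last is IC; stances are
   the intervals between swings, discarded below 0.1 s.
6. **Validation without force plates** (`impulse_validation`): per-stance
   braking/propulsion impulses (Simpson integration over the stance, %BW·s,
   signed) against per-stance speed (mean of the speed trace over the
   stance).  Stances are binned into 25 half-open speed bins
   [2.0+0.1k, 2.1+0.1k), k = 0…24; bins with fewer than three stances are
   dropped.  A weighted linear model is fit to all member observations
   with per-bin weights w_i = 1/σ_i² (σ² floored at 1e-8 when a bin is
   degenerate); fits from predictions and from force plates are compared
   by the RMSE of the two lines on the 25 bin centers (2.05…4.45 m/s).

## Training modes and experiment design

* **Generalized (GEN-TM)**: pooled treadmill stance windows of all
  training runners, 9:1 random train/validation split over stances,
  40 epochs, batch 32.  Normalization ranges (grouped min-max, one range
  per sensor-modality triple so tri-axial channels keep their relative
  magnitudes; each sagittal angle is its own group) are fit on the
  training windows only and reused unchanged at validation/test/inference.
* **Fine-tuned (FTN-TM / FTN-OG)**: continues training *all* weights on
  the chronologically first k stances of the held-out runner (treadmill
  or overground; a seeded random-selection mode is available behind
  ``ft_selection="random"``), 15 epochs, batch 16, with a fixed
  four-stance validation set taken from the end of the fine-tune pool so
  it does not change with k.  The pre-trained normalization is kept: the inputs must
  stay on the scale the weights were trained with.
* **Individual (IND-OG)**: same k stances, fresh initialization, batch 1,
  own normalization.
* **Evaluation**: leave-one-runner-out; a held-out runner's overground
  stances are split chronologically (first half = fine-tune pool A,
  second half = test set B).  Errors are stance-restricted RMSE in %BW,
  pooled over test-stance frames — swing frames are excluded so trivially
  correct near-zero swing predictions cannot improve the score.  The best
  validation-loss checkpoint is used (the final-epoch state is also
  retained); targets stay in raw %BW (no target normalization) because
  errors are reported in %BW and the swing target is exactly zero.

Model-selection details chosen here (read-out at the mid-point timestep
of the bidirectional stack, ReLU dense activations, AdamW weight decay
0.01, smooth-L1 β = 1) are recorded in each estimator's provenance
alongside the training config, seed and SHA-1 fingerprints of every
training window; experiment drivers assert train/test fingerprint
disjointness on every fold.

## The synthetic cohort

The simulator emulates the statistical structure the pipeline relies on,
not musculoskeletal physics:

* **Gait**: per-runner cadence (U(155, 180) steps/min), duty factor
  (U(0.32, 0.40)), ±2 % per-stride period jitter; unilateral stances.
* **Force**: per stance, a negative half-sine braking lobe over the first
  45 % of stance followed by a positive half-sine propulsion lobe; peak
  amplitudes are gain × speed with per-runner gains U(3.5, 6.0) %BW per
  (m/s) (≈15 %BW peaks at 3 m/s).  Vertical force is a 2.5-bodyweight
  half-sine over stance, synthesized at 2 kHz like the AP channel.
  Impulses are therefore exactly linear in speed with known slope
  2·gain·lobe-duration/π.
* **Kinematics**: sagittal segment angles are stride-phase sinusoids
  whose amplitudes encode the same gains that set the force amplitudes
  (shank ↔ braking, foot ↔ propulsion), multiplied by per-runner style
  factors U(0.85, 1.15); gyroscopes are the angle derivatives;
  accelerometers see gravity rotated by the segment angle, a smooth AP
  acceleration proportional to the force shape, and a decaying 25 Hz
  axial impact transient at contact.  Because style factors multiply the
  observable amplitudes but not the force, a generalized model can only
  learn the cohort-average mapping — individual fine-tuning has something
  real to recover.
* **Domain shift**: overground and outdoor settings multiply the
  propulsion amplitude by 1.2 and offset the foot angle at contact by 5°,
  while the kinematic channels keep their treadmill-calibrated
  amplitude-to-force relationship.  A treadmill-trained model therefore
  underestimates overground propulsion systematically until fine-tuned on
  overground data — the controlled analogue of the treadmill→overground
  transfer problem.  Outdoor sessions additionally carry extra sensor
  noise and expose no force channels (truth is retained in a sidecar for
  evaluation only).
* **Noise**: i.i.d. Gaussian per channel (0.4 m/s² acc, 4 °/s gyro,
  0.4° angle by default; outdoors +0.3/+3/+0.3).
* **Speed**: piecewise-constant schedules (a new speed from U(2.4, 4.2)
  m/s every 15 s), emulating protocols in which runners periodically
  change pace; per-stance truth speed is the schedule value at contact.

What passing tests on this cohort show: the implementation learns a
learnable smooth mapping, transfers across the constructed domain shift in
the expected direction, and all bookkeeping (splits, normalization,
segmentation, integration, fitting) is correct.  What they cannot show:
performance on real tissue-artifact-laden IMU signals, real inter-runner
variability, surface/footwear effects, or absolute error levels
comparable to human datasets.

## Problem sizes of the reference study

The desk-scale study (`runkinetics.study`, also behind
`scripts/acceptance.py`) uses six runners with 105 s sessions (~140
stances each; three runners also get an outdoor session), three seeds,
and leave-one-runner-out folds.  Scaling choices, applied uniformly to
every configuration: generalized training 3 epochs with training
sub-sequence stride 12, fine-tuning 5 epochs at stride 2 (inference is
always hop 1), individual training 3 epochs, individual models trained at
k = 8 only, and the 45 chronologically first test stances of split B
scored per fold.  These sizes keep a full study around a quarter of an
hour on one CPU while leaving the qualitative comparisons (generalized
vs fine-tuned vs individual, stride sweep, impulse-fit validation)
clearly resolved.

## Numerical choices and edge cases

* Zero-phase filtering pads with `padtype='odd'`, `padlen = 3·(order+1)`;
  ramps pass unchanged; series must exceed the pad length.  The
  time-reversal symmetry of the ideal zero-phase filter holds to 1e-6
  away from a ~60-sample boundary transient.
* Force resampling uses a natural cubic spline (exact on constants and
  ramps, O(h⁴) interior error on band-limited content).
* Impulse integration uses Simpson's rule on the sampled stance
  (trapezoid error on a 6-sample half-sine lobe is ~2 %, Simpson ~0.1 %);
  the braking/propulsion decomposition identity is exact by linearity.
* The swing-rule slope test is signed by default (`y[t] − y[t−1] ≤ 0.25`):
  a steep drop onto the near-zero band still opens a swing run, which
  pins TO to the first near-zero frame; an absolute variant is available.
  The run-length threshold is ≥ 5 frames (41.7 ms at 120 Hz).
* The sub-sequence mid-point of the even length-22 window is 0-based
  index 11.
* When training sub-sequences are subsampled (stride > 1), each window
  receives a seeded random phase offset in [0, stride): all windows start
  at IC − 29, so a fixed subsampling grid would expose the model to only
  a handful of stance-phase alignments while inference slides at hop 1 —
  the offset restores full phase coverage at unchanged cost.
* Gait-event scoring matches each predicted event to the nearest true
  event within half the median true stride period; unmatched events are
  counted, not scored.
* Degenerate cases raise explicit errors: normalization groups with
  max = min, fewer than two surviving speed bins, sessions shorter than
  22 frames, empty training sets, generalized training with fewer than
  two runners, duration too short for one stride.
* Sagittal-angle extraction is a complementary split at 0.3 Hz between
  the accelerometer inclination (atan2 of the gravity components) and the
  integrated medio-lateral angular rate; it raises when the gravity
  estimate is degenerate (mean sagittal acceleration norm < 1 m/s²).

## Known limitations

* The simulator's channels are low-dimensional sinusoids; real IMU data
  contain soft-tissue artifacts, sensor drift and orientation error that
  the pipeline's filtering cannot remove and the tests do not probe.
* Only straight-line, level running is modeled; straightaway extraction
  from GPS/marker coordinates is out of scope (synthetic sessions are
  straight by construction).
* The numpy training loop is single-threaded CPU code; it is sized for
  cohorts of tens of runners, not thousands.
* Impulse validation assumes an approximately linear impulse-speed
  relationship over 2–4.5 m/s; outside that speed range stances are
  logged and ignored.
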