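# runkinetics

Estimation of braking and propulsion forces — the anterior-posterior
component of the ground reaction force (AP-GRF) — during running, from
body-worn inertial measurement units (IMUs).

Measuring AP-GRF normally requires force plates or an instrumented
treadmill, which confines kinetic analysis to the lab.  `runkinetics`
implements a complete wearable-sensor alternative for researchers in
running biomechanics:

* a **recurrent regressor** (two bidirectional LSTM layers of 64 units,
  dense 128/64 head, output read at the sub-sequence mid-point) that maps
  22-frame windows of 27 inertial channels — tri-axial acceleration and
  angular velocity of pelvis, thigh, shank and foot, plus drift-corrected
  sagittal angles of thigh/shank/foot at 120 Hz — to AP-GRF in percent
  bodyweight (%BW);
* **three training modes**: generalized training on pooled treadmill data
  of many runners (smooth-L1 loss, AdamW, lr 0.001, 40 epochs, batch 32,
  9:1 train/validation split), fine-tuning of all weights on a handful of
  an individual's stances (15 epochs, batch 16, 4 validation stances), and
  individual-only training from scratch (batch 1);
* **gait segmentation** both ways: force-threshold stance extraction
  (20 N on vertical force, stances extended by 29 frames ≈ 0.242 s of
  swing context) for training, and prediction-based swing detection
  (≥ 5 consecutive frames with |y| ≤ 0.5 %BW and slope ≤ 0.25 %BW/frame)
  for continuous force-plate-free inference;
* **speed-impulse validation** for settings without any force reference:
  per-stance braking/propulsion impulses (∫F dt over the negative/positive
  lobes, %BW·s) are binned into 25 speed bins of 0.1 m/s over
  [2.0, 4.5) m/s, fit with inverse-variance-weighted least squares
  (w_i = 1/σ_i²), and compared to a force-plate reference line by RMSE
  over the 25 bin centers;
* a **synthetic gait simulator** that generates multi-runner cohorts with
  known ground truth — half-sine braking/propulsion lobes whose amplitudes
  scale linearly with speed, per-runner gains and style factors, and a
  controlled treadmill→overground domain shift — so the entire pipeline is
  testable end to end without human-subject data.

The recurrent network, its analytic backpropagation and the AdamW
optimizer are implemented in numpy (`runkinetics.nn`) and run on a single
CPU.

## Worked example

`examples/train_and_finetune.py` trains a generalized model on two
synthetic runners' treadmill sessions, fine-tunes it on eight overground
stances of a third, held-out runner, and evaluates on that runner's
remaining overground stances:

```
configuration  stride_count  stance_rmse_bw
         ZERO           NaN       13.319096
       GEN-TM           NaN        8.156968
       FTN-OG           8.0        2.604314
       IND-OG           8.0       13.260844
```

`stance_rmse_bw` is the RMSE (in %BW) between predicted and force-plate
AP-GRF pooled over the held-out runner's test stance frames (swing frames
are excluded so near-zero swing predictions cannot flatter the score).
`ZERO` — the all-zero baseline — equals the RMS of the true signal (about
13.3 %BW here).  The treadmill-trained generalized model (`GEN-TM`)
roughly halves that, fine-tuning with eight of the runner's own overground
stances (`FTN-OG`) takes it below 3 %BW, while a model trained from
scratch on those same eight stances (`IND-OG`) barely beats the baseline:
transfer plus individualization beats either alone.

Other entry points: `examples/simulate_dataset.py` (cohort generation and
ground truth), `examples/condition_and_segment.py` (filtering, %BW
conversion, stance windows), `examples/event_detection.py` (swing-rule
gait events and their timing error), `examples/impulse_speed_validation.py`
(weighted impulse-speed fits and line comparison).  A thin CLI wraps the
same functions: `runkinetics simulate|train|finetune|predict|experiment|validate`.

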