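"""Detect gait events from an AP-GRF waveform with the swing rule.

Swing phases are runs of at least five consecutive near-zero frames
(|y| <= 0.5 %BW, slope <= 0.25 %BW/frame); toe-off is a run's first frame
and initial contact the frame after its last.  Here the rule is applied to
a noise-free synthetic waveform and scored against the generator's truth.
"""

from runkinetics import SettingShift, SimConfig, generate_runner, generate_session
from runkinetics.segmentation import (
    SwingRule,
    detect_gait_events_from_prediction,
    event_rmse,
)
from runkinetics.segmentation import GaitEvents

profile = generate_runner(12)
profile.noise_sd = {"acc": 0.0, "gyro": 0.0, "angle": 0.0}
session, truth = generate_session(profile, SettingShift.treadmill(),
                                  SimConfig(seed=4, duration=60.0))

events = detect_gait_events_from_prediction(truth.ap_grf_bw, SwingRule(),
                                            session.frame_rate)
truth_events = GaitEvents(truth.ic_frames, truth.to_frames)
scores = event_rmse(events, truth_events, session.frame_rate)

print(f"true stances: {truth.n_stances}, detected: {events.n_stances}")
print(f"IC timing RMSE: {scores['ic_rmse_s']*1000:.1f} ms "
      f"({scores['ic_unmatched']} unmatched)")
print(f"TO timing RMSE: {scores['to_rmse_s']*1000:.1f} ms "
      f"({scores['to_unmatched']} unmatched)")
print("\nOn a clean waveform both events land within ~2 frames (17 ms);")
print("on model predictions the error reflects estimation quality as well.")
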