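"""Condition a raw session and segment it into training windows.

Shows the pre-processing chain: zero-phase 50 Hz low-pass filtering of the
IMU channels, 50 Hz filtering + resampling of the 2 kHz force plates onto
the 120 Hz frame grid, conversion to %BW, 20 N stance detection and the
+-29-frame window extension used for model training.
"""

import numpy as np

from runkinetics import SettingShift, SimConfig, generate_runner, generate_session
from runkinetics.experiments import prepare_session

profile = generate_runner(7)
session, truth = generate_session(profile, SettingShift.treadmill(),
                                  SimConfig(seed=3, duration=30.0))
print(f"runner mass {profile.mass:.1f} kg, cadence "
      f"{profile.cadence_base:.0f} steps/min, duty factor "
      f"{profile.duty_factor:.2f}")

prep = prepare_session(session)
ev = prep.events
print(f"\nforce-threshold segmentation: {ev.n_stances} stances "
      f"(generator truth: {truth.n_stances})")
dur = (ev.to_frames - ev.ic_frames) / session.frame_rate
print(f"stance duration {dur.mean()*1000:.0f} +- {dur.std()*1000:.0f} ms")

w = prep.windows[0]
print(f"\nfirst training window: stance frames [{w.stance_start}, "
      f"{w.stance_end}), window frames [{w.window_start}, {w.window_end}) "
      f"-> {w.n_frames} frames of {w.inputs.shape[1]} channels")
print(f"peak braking  {prep.ap_bw[w.stance_start:w.stance_end].min():.1f} %BW")
print(f"peak propulsion {prep.ap_bw[w.stance_start:w.stance_end].max():.1f} %BW")
print("\nwindows include 29 frames (0.242 s) of swing context on each side,")
print("so a trained model can run over continuous multi-stride recordings.")
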