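"""Recording container and plain-text I/O.

A :class:`SensorSession` holds one continuous recording of a runner: the
inertial channels sampled at the IMU rate (120 Hz by default), optional
force-plate channels at their own (higher) rate, a per-frame running-speed
trace, and session metadata.  Ground-truth kinetics and gait events for
synthetic recordings live in a separate :class:`GroundTruth` object that the
estimation pipeline never reads; it is persisted to a sidecar file so that
tests and evaluation code can consult it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Body segments carrying an IMU.
SEGMENTS = ("pelvis", "thigh", "shank", "foot")
#: Segments with a drift-corrected sagittal angle channel (pelvis has none).
ANGLE_SEGMENTS = ("thigh", "shank", "foot")
AXES = ("x", "y", "z")

#: Recording settings: treadmill / overground with force plates, overground
#: and outdoor without.
SETTINGS = ("TM-FP", "OG-FP", "OG", "OUT")

STANDARD_GRAVITY = 9.80665  # m/s^2


def inertial_channel_names() -> list[str]:
    """Names of the 24 inertial channels (4 segments x (3 acc + 3 gyro))."""
    names = []
    for seg in SEGMENTS:
        names += [f"{seg}_acc_{ax}" for ax in AXES]
        names += [f"{seg}_gyro_{ax}" for ax in AXES]
    return names


def angle_channel_names() -> list[str]:
    return [f"angle_{seg}" for seg in ANGLE_SEGMENTS]


def all_channel_names() -> list[str]:
    """The full 27-channel model input set."""
    return inertial_channel_names() + angle_channel_names()


@dataclass
class SensorSession:
    """One continuous recording of a single runner.

    Parameters
    ----------
    participant_id
        Runner identifier.
    setting
        One of ``TM-FP``, ``OG-FP``, ``OG``, ``OUT``.
    frame_rate
        IMU sampling rate in Hz.
    channels
        Frame-indexed DataFrame with one named column per channel
        (acc in m/s^2, gyro in deg/s, angles in deg).
    bodyweight
        Body weight in newtons (mass * g).
    speed_trace
        Running speed in m/s per IMU frame, or ``None``.
    force_vertical, force_ap
        Optional force-plate channels in newtons at ``force_rate`` Hz.
    """

    participant_id: str
    setting: str
    frame_rate: float
    channels: pd.DataFrame
    bodyweight: float
    speed_trace: Optional[np.ndarray] = None
    force_vertical: Optional[np.ndarray] = None
    force_ap: Optional[np.ndarray] = None
    force_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.force_vertical is not None and self.force_ap is not None:
            if len(self.force_vertical) != len(self.force_ap):
                raise ValueError("force channels have unequal lengths")

    @property
    def n_frames(self) -> int:
        return len(self.channels)

    @property
    def has_force(self) -> bool:
        return self.force_vertical is not None

    def channel_matrix(self, names: Optional[list[str]] = None) -> np.ndarray:
        """Return a (frames, channels) array in the given column order."""
        names = list(names) if names is not None else list(self.channels.columns)
        return self.channels[names].to_numpy(dtype=float)


@dataclass
class GroundTruth:
    """Hidden truth for a synthetic session (never read by the estimators).

    ``ap_grf_bw`` is the anterior-posterior GRF in %BW on the IMU frame grid;
    ``ic_frames``/``to_frames`` are initial-contact and toe-off frame indices
    (stance ``k`` spans frames ``[ic_frames[k], to_frames[k])``);
    ``stance_speeds`` is the running speed of each stance in m/s.
    """

    ap_grf_bw: np.ndarray
    ic_frames: np.ndarray
    to_frames: np.ndarray
    stance_speeds: np.ndarray
    braking_impulses: Optional[np.ndarray] = None
    propulsion_impulses: Optional[np.ndarray] = None
    ic_times_s: Optional[np.ndarray] = None    # exact (off-grid) event times
    to_times_s: Optional[np.ndarray] = None
    angle_truth: Optional[pd.DataFrame] = None

    @property
    def n_stances(self) -> int:
        return len(self.ic_frames)


# ---------------------------------------------------------------------------
# Plain-text persistence
# ---------------------------------------------------------------------------

def write_session(session: SensorSession, directory: str | Path) -> Path:
    """Write a session as CSV files plus a JSON manifest; return the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    session.channels.to_csv(directory / "channels.csv", index_label="frame")
    meta = {
        "participant_id": session.participant_id,
        "setting": session.setting,
        "frame_rate": session.frame_rate,
        "bodyweight": session.bodyweight,
        "force_rate": session.force_rate,
    }
    (directory / "session.json").write_text(json.dumps(meta, indent=2))
    if session.speed_trace is not None:
        pd.DataFrame({"speed": session.speed_trace}).to_csv(
            directory / "speed.csv", index_label="frame")
    if session.has_force:
        pd.DataFrame({
            "vertical": session.force_vertical,
            "ap": session.force_ap,
        }).to_csv(directory / "force.csv", index_label="sample")
    return directory


def read_session(directory: str | Path) -> SensorSession:
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    channels = pd.read_csv(directory / "channels.csv", index_col="frame")
    speed = None
    if (directory / "speed.csv").exists():
        speed = pd.read_csv(directory / "speed.csv")["speed"].to_numpy()
    fv = fap = None
    if (directory / "force.csv").exists():
        force = pd.read_csv(directory / "force.csv")
        fv = force["vertical"].to_numpy()
        fap = force["ap"].to_numpy()
    return SensorSession(
        participant_id=meta["participant_id"],
        setting=meta["setting"],
        frame_rate=meta["frame_rate"],
        channels=channels,
        bodyweight=meta["bodyweight"],
        speed_trace=speed,
        force_vertical=fv,
        force_ap=fap,
        force_rate=meta.get("force_rate"),
    )


def write_truth(truth: GroundTruth, directory: str | Path) -> Path:
    """Persist ground truth to sidecar CSVs (evaluation only)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"ap_grf_bw": truth.ap_grf_bw}).to_csv(
        directory / "truth_waveform.csv", index_label="frame")
    events = pd.DataFrame({
        "ic_frame": truth.ic_frames,
        "to_frame": truth.to_frames,
        "speed": truth.stance_speeds,
    })
    if truth.braking_impulses is not None:
        events["braking_impulse"] = truth.braking_impulses
        events["propulsion_impulse"] = truth.propulsion_impulses
    if truth.ic_times_s is not None:
        events["ic_time_s"] = truth.ic_times_s
        events["to_time_s"] = truth.to_times_s
    events.to_csv(directory / "truth_events.csv", index_label="stance")
    return directory


def read_truth(directory: str | Path) -> GroundTruth:
    directory = Path(directory)
    wf = pd.read_csv(directory / "truth_waveform.csv")["ap_grf_bw"].to_numpy()
    ev = pd.read_csv(directory / "truth_events.csv")
    return GroundTruth(
        ap_grf_bw=wf,
        ic_frames=ev["ic_frame"].to_numpy(),
        to_frames=ev["to_frame"].to_numpy(),
        stance_speeds=ev["speed"].to_numpy(),
        braking_impulses=ev["braking_impulse"].to_numpy()
        if "braking_impulse" in ev else None,
        propulsion_impulses=ev["propulsion_impulse"].to_numpy()
        if "propulsion_impulse" in ev else None,
        ic_times_s=ev["ic_time_s"].to_numpy() if "ic_time_s" in ev else None,
        to_times_s=ev["to_time_s"].to_numpy() if "to_time_s" in ev else None,
    )
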