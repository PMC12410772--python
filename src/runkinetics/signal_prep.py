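"""Signal conditioning: filtering, resampling, normalization, angles, sync.

All conditioning steps of the estimation pipeline live here:

* zero-phase (forward-backward) fourth-order Butterworth low-pass filtering;
* resampling of force-plate channels onto the IMU frame grid;
* body-weight normalization of forces to %BW;
* drift-corrected sagittal segment angles from accelerometer + gyroscope;
* cross-correlation time alignment between a reference angle and an
  IMU-derived angle;
* grouped min-max normalization of the model inputs, fit on training data
  only, with tri-axial channels of one sensor sharing a single (min, max)
  pair so that relative magnitudes are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import signal

from .session import (
    ANGLE_SEGMENTS,
    AXES,
    SEGMENTS,
    STANDARD_GRAVITY,
    SensorSession,
)


@dataclass
class FilterSpec:
    """Low-pass Butterworth specification (bidirectional = zero-phase)."""

    cutoff_hz: float
    order: int = 4
    bidirectional: bool = True


def butter_filter(series: np.ndarray, spec: FilterSpec,
                  sample_rate: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter, same length as the input.

    Uses forward-backward filtering with odd-reflect padding of length
    ``3 * (order + 1)`` so that ramps pass through unchanged.  Raises
    ``ValueError`` for series shorter than the padding requires or for a
    cutoff at/above Nyquist.
    """
    series = np.asarray(series, dtype=float)
    nyq = sample_rate / 2.0
    if not 0 < spec.cutoff_hz < nyq:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz outside (0, {nyq}) Hz")
    padlen = 3 * (spec.order + 1)
    if series.shape[-1] <= padlen:
        raise ValueError(f"series too short for zero-phase filtering "
                         f"(need > {padlen} samples, got {series.shape[-1]})")
    b, a = signal.butter(spec.order, spec.cutoff_hz / nyq, btype="low")
    if spec.bidirectional:
        return signal.filtfilt(b, a, series, padtype="odd", padlen=padlen)
    return signal.lfilter(b, a, series)


def resample_force_to_imu(force: np.ndarray, force_rate: float,
                          n_frames: int, frame_rate: float) -> np.ndarray:
    """Interpolate a force series onto the IMU frame timestamps.

    The force series is assumed already band-limited (low-pass filtered at
    50 Hz) so interpolation onto the 120 Hz grid is alias-safe.  A natural
    cubic spline is used: it reproduces constants and ramps exactly and
    tracks band-limited content far better than linear interpolation
    (interior error O(h^4) in the source spacing).  IMU timestamps beyond
    the force record are extrapolated by the spline's end segments.
    """
    from scipy.interpolate import CubicSpline
    force = np.asarray(force, dtype=float)
    if len(force) < 2:
        raise ValueError("force series too short to resample")
    t_force = np.arange(len(force)) / force_rate
    t_imu = np.arange(n_frames) / frame_rate
    spline = CubicSpline(t_force, force, bc_type="natural")
    return spline(t_imu)


def force_to_percent_bw(force_n: np.ndarray, bodyweight_n: float = None, *,
                        mass_kg: float = None) -> np.ndarray:
    """Convert a force in newtons to percent body weight.

    Either ``bodyweight_n`` (N) or ``mass_kg`` may be given; with a mass,
    body weight is ``mass * 9.80665``.
    """
    if bodyweight_n is None:
        if mass_kg is None:
            raise ValueError("provide bodyweight_n or mass_kg")
        bodyweight_n = mass_kg * STANDARD_GRAVITY
    if bodyweight_n <= 0:
        raise ValueError("bodyweight must be positive")
    return 100.0 * np.asarray(force_n, dtype=float) / bodyweight_n


def extract_sagittal_angle(acc: np.ndarray, gyro: np.ndarray,
                           sample_rate: float,
                           drift_cutoff_hz: float = 0.3) -> np.ndarray:
    """Drift-corrected sagittal segment angle (deg) about the joint axis.

    Assumes the sensor's y axis is aligned with the joint (medio-lateral)
    axis, so the sagittal angle is the rotation about y between the sensor
    frame and the gravity-aligned global frame.  The low-frequency part of
    the angle comes from the gravity direction in the low-passed
    accelerometer (``atan2(a_x, a_z)``), the high-frequency part from the
    integrated medio-lateral angular velocity — a complementary split at
    ``drift_cutoff_hz`` that removes gyroscope drift while rejecting
    linear-acceleration corruption of the gravity estimate.

    Parameters
    ----------
    acc : (n, 3) accelerometer in m/s^2 (sensor frame)
    gyro : (n, 3) angular velocity in deg/s (sensor frame)
    """
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("acc must be (n, 3)")
    norm = np.hypot(acc[:, 0], acc[:, 2])
    if np.mean(norm) < 1.0:
        raise ValueError("gravity estimate degenerate: low-passed "
                         "acceleration norm near zero")
    incl = np.degrees(np.unwrap(np.arctan2(acc[:, 0], acc[:, 2])))
    gyro_int = np.concatenate([[0.0],
                               np.cumsum((gyro[1:, 1] + gyro[:-1, 1]) / 2.0)
                               ]) / sample_rate
    spec = FilterSpec(cutoff_hz=drift_cutoff_hz, order=4)
    lp_incl = butter_filter(incl, spec, sample_rate)
    lp_gyro = butter_filter(gyro_int, spec, sample_rate)
    return lp_incl + (gyro_int - lp_gyro)


def acceleration_to_global(acc: np.ndarray,
                           sagittal_angle_deg: np.ndarray) -> np.ndarray:
    """Rotate sensor-frame accelerations into the gravity-aligned frame.

    Applies the per-frame rotation about the joint (y) axis given by the
    sensor's sagittal orientation estimate, so accelerations of all
    segments share one global reference frame.  ``acc`` is (n, 3) in m/s^2;
    a static sensor tilted by any angle maps to (0, 0, g).
    """
    acc = np.asarray(acc, dtype=float)
    th = np.deg2rad(np.asarray(sagittal_angle_deg, dtype=float))
    c, s = np.cos(th), np.sin(th)
    out = np.empty_like(acc)
    out[:, 0] = c * acc[:, 0] - s * acc[:, 2]
    out[:, 1] = acc[:, 1]
    out[:, 2] = s * acc[:, 0] + c * acc[:, 2]
    return out


def sync_by_cross_correlation(reference: np.ndarray,
                              candidate: np.ndarray,
                              max_lag: Optional[int] = None) -> int:
    """Integer lag (frames) by which ``candidate`` trails ``reference``.

    The returned lag maximizes the normalized cross-correlation; shifting
    the candidate *back* by this lag aligns it with the reference.  A
    positive lag means the candidate is delayed relative to the reference.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    ref = (ref - ref.mean()) / (ref.std() or 1.0)
    cand = (cand - cand.mean()) / (cand.std() or 1.0)
    corr = signal.correlate(cand, ref, mode="full")
    lags = signal.correlation_lags(len(cand), len(ref), mode="full")
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        corr, lags = corr[keep], lags[keep]
    return int(lags[np.argmax(corr)])


# ---------------------------------------------------------------------------
# Grouped min-max normalization
# ---------------------------------------------------------------------------

def default_groups(channel_names: Iterable[str]) -> dict[str, list[str]]:
    """One group per (sensor, modality); each angle is its own group.

    Tri-axial acceleration (and angular-velocity) channels of one sensor
    share a group so normalization retains their relative magnitudes.
    """
    channel_names = list(channel_names)
    groups: dict[str, list[str]] = {}
    for seg in SEGMENTS:
        for mod in ("acc", "gyro"):
            members = [f"{seg}_{mod}_{ax}" for ax in AXES
                       if f"{seg}_{mod}_{ax}" in channel_names]
            if members:
                groups[f"{seg}_{mod}"] = members
    for seg in ANGLE_SEGMENTS:
        name = f"angle_{seg}"
        if name in channel_names:
            groups[name] = [name]
    leftovers = [c for c in channel_names
                 if not any(c in m for m in groups.values())]
    for c in leftovers:
        groups[c] = [c]
    return groups


@dataclass
class NormalizationSpec:
    """Per-group (min, max) learned from training data only."""

    groups: Mapping[str, list[str]]
    ranges: Mapping[str, tuple[float, float]]

    def to_json(self, path: str | Path) -> None:
        payload = {"groups": {k: list(v) for k, v in self.groups.items()},
                   "ranges": {k: [float(a), float(b)]
                              for k, (a, b) in self.ranges.items()}}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationSpec":
        payload = json.loads(Path(path).read_text())
        return cls(groups=payload["groups"],
                   ranges={k: (v[0], v[1])
                           for k, v in payload["ranges"].items()})


def fit_normalization(frames: pd.DataFrame | Iterable[pd.DataFrame],
                      groups: Optional[dict[str, list[str]]] = None
                      ) -> NormalizationSpec:
    """Learn grouped min-max ranges from training data.

    ``frames`` is a channel DataFrame or an iterable of them (e.g. the input
    matrices of all training stance windows).  Raises ``ValueError`` for a
    degenerate group (max == min).
    """
    if isinstance(frames, pd.DataFrame):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise ValueError("no training data")
    if groups is None:
        groups = default_groups(frames[0].columns)
    ranges = {}
    for name, members in groups.items():
        lo = min(float(f[members].to_numpy().min()) for f in frames)
        hi = max(float(f[members].to_numpy().max()) for f in frames)
        if hi <= lo:
            raise ValueError(f"degenerate normalization group {name!r}: "
                             f"max ({hi}) <= min ({lo})")
        ranges[name] = (lo, hi)
    return NormalizationSpec(groups=groups, ranges=ranges)


def apply_normalization(frame: pd.DataFrame,
                        spec: NormalizationSpec) -> pd.DataFrame:
    """Map each group by ``(x - min_g) / (max_g - min_g)``; no clipping."""
    out = frame.copy()
    for name, members in spec.groups.items():
        lo, hi = spec.ranges[name]
        cols = [c for c in members if c in out.columns]
        if cols:
            out[cols] = (out[cols] - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# Session-level conditioning
# ---------------------------------------------------------------------------

def condition_session(session: SensorSession,
                      imu_cutoff_hz: float = 50.0) -> SensorSession:
    """Filter the IMU channels and resample force onto the IMU grid.

    Returns a new session whose channels are low-pass filtered (zero-phase
    fourth-order Butterworth, 50 Hz cutoff by default) and whose force
    channels, if present, are low-pass filtered at 50 Hz at their native
    rate and linearly resampled to the IMU frame grid (``force_rate``
    becomes the IMU rate).
    """
    spec = FilterSpec(cutoff_hz=imu_cutoff_hz, order=4)
    filtered = session.channels.apply(
        lambda col: butter_filter(col.to_numpy(), spec, session.frame_rate),
        axis=0)
    fv = fap = None
    new_rate = None
    if session.has_force:
        fspec = FilterSpec(cutoff_hz=50.0, order=4)
        fv = butter_filter(session.force_vertical, fspec, session.force_rate)
        fap = butter_filter(session.force_ap, fspec, session.force_rate)
        fv = resample_force_to_imu(fv, session.force_rate,
                                   session.n_frames, session.frame_rate)
        fap = resample_force_to_imu(fap, session.force_rate,
                                    session.n_frames, session.frame_rate)
        new_rate = session.frame_rate
    return SensorSession(
        participant_id=session.participant_id,
        setting=session.setting,
        frame_rate=session.frame_rate,
        channels=filtered,
        bodyweight=session.bodyweight,
        speed_trace=session.speed_trace,
        force_vertical=fv,
        force_ap=fap,
        force_rate=new_rate,
    )
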