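"""Synthetic running-gait simulator with known AP-GRF ground truth.

The simulator produces multi-runner, multi-setting recordings that mimic the
statistical structure an IMU-to-force estimation pipeline relies on:

* stance/swing gait structure at realistic cadences and duty factors;
* an anterior-posterior GRF per stance shaped as a negative half-sine braking
  lobe followed by a positive half-sine propulsion lobe, with amplitudes that
  grow linearly with running speed (so per-stance impulses are linear in
  speed by construction);
* smooth inertial channels (sagittal segment-angle sinusoids, their
  derivatives, gravity components, an impact transient at initial contact)
  that are deterministic functions of gait phase and of the same per-runner
  gains that set the force amplitudes — so the IMU-to-force mapping is
  learnable by construction;
* per-runner individuality (gains, cadence, duty factor, multiplicative
  channel "style" factors a generalized model cannot disentangle from the
  gains without that runner's data);
* a systematic treadmill-to-overground domain shift: overground propulsion
  amplitude is multiplied by ``propulsion_shift`` and the foot angle at
  contact is offset by ``foot_angle_shift`` degrees, while the kinematic
  channels otherwise keep their treadmill-calibrated amplitude-to-force
  relationship.  A treadmill-trained model therefore misestimates overground
  propulsion until it is fine-tuned on overground data.

Force-plate channels are synthesized at a higher rate (2 kHz by default,
mirroring laboratory instrumentation) and the IMU channels at 120 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .session import (
    GroundTruth,
    SensorSession,
    STANDARD_GRAVITY,
    all_channel_names,
)

# Fraction of stance occupied by the braking lobe; the remainder is the
# propulsion lobe.  Fixed waveform constants of the simulator.
BRAKING_FRACTION = 0.45

# Impact-transient shape at initial contact (axial shock on the acc channels).
_IMPACT_TAU_S = 0.03
_IMPACT_FREQ_HZ = 25.0
_IMPACT_AMP = {"foot": 8.0, "shank": 5.0, "thigh": 2.5, "pelvis": 1.5}  # m/s^2 at 3 m/s

# Segment-angle waveform constants (deg); see docs/methods.md.
_PHASE = {"thigh": 0.0, "shank": 2.1, "foot": 4.0, "pelvis": 1.0}
_SHANK_ANGLE_PER_GAIN = 1.1   # deg per (%BW of braking amplitude)
_FOOT_ANGLE_PER_GAIN = 1.0    # deg per (%BW of propulsion amplitude)
_LIN_ACC_SCALE = {"foot": 0.15, "shank": 0.10, "thigh": 0.05, "pelvis": 0.08}
# m/s^2 of kinematic AP acceleration per %BW of (unshifted) force amplitude

_DEFAULT_NOISE_SD = {"acc": 0.4, "gyro": 4.0, "angle": 0.4}
_VERTICAL_PEAK_BW = 2.5  # vertical GRF peak in bodyweights


@dataclass
class RunnerProfile:
    """Per-runner gait parameters.

    ``braking_gain`` and ``propulsion_gain`` are the %BW-per-(m/s) scalings
    of the braking/propulsion lobe amplitudes with running speed; at 3 m/s a
    gain of 5 gives a 15 %BW lobe peak, typical of recreational runners.
    ``style_offsets`` holds the multiplicative/additive channel individuality
    parameters; ``noise_sd`` the per-modality measurement noise scales.
    """

    runner_id: str
    mass: float                  # kg
    cadence_base: float          # steps/min (both legs)
    duty_factor: float           # stance fraction of the stride period
    braking_gain: float          # %BW per (m/s)
    propulsion_gain: float       # %BW per (m/s)
    style_offsets: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if not 0.2 <= self.duty_factor <= 0.45:
            raise ValueError("duty_factor outside [0.2, 0.45]")
        if self.braking_gain <= 0 or self.propulsion_gain <= 0:
            raise ValueError("gains must be positive")

    @property
    def bodyweight(self) -> float:
        """Body weight in newtons."""
        return self.mass * STANDARD_GRAVITY


@dataclass
class SettingShift:
    """Systematic differences of a recording setting relative to treadmill.

    ``propulsion_shift`` multiplies the propulsion lobe amplitude;
    ``foot_angle_shift`` offsets the sagittal foot angle (deg), emulating the
    altered foot posture at contact overground; ``extra_noise_sd`` adds
    per-modality measurement noise (outdoors).
    """

    setting: str
    propulsion_shift: float = 1.0
    foot_angle_shift: float = 0.0
    extra_noise_sd: dict = field(default_factory=dict)

    @classmethod
    def treadmill(cls) -> "SettingShift":
        return cls(setting="TM-FP")

    @classmethod
    def overground(cls, propulsion_shift: float = 1.2,
                   foot_angle_shift: float = 5.0,
                   with_force: bool = True) -> "SettingShift":
        return cls(setting="OG-FP" if with_force else "OG",
                   propulsion_shift=propulsion_shift,
                   foot_angle_shift=foot_angle_shift)

    @classmethod
    def outdoor(cls, propulsion_shift: float = 1.2,
                foot_angle_shift: float = 5.0) -> "SettingShift":
        return cls(setting="OUT",
                   propulsion_shift=propulsion_shift,
                   foot_angle_shift=foot_angle_shift,
                   extra_noise_sd={"acc": 0.3, "gyro": 3.0, "angle": 0.3})


@dataclass
class SimConfig:
    """Simulation configuration.

    ``speed_schedule`` is a piecewise-constant speed profile given as
    ``[(start_time_s, speed_m_s), ...]``; when ``None`` a schedule with a new
    speed drawn from ``speed_range`` every ``speed_segment_s`` seconds is
    generated (emulating a protocol in which runners periodically increase or
    decrease their speed).
    """

    seed: int
    duration: float = 60.0
    sample_rate: float = 120.0
    force_rate: float = 2000.0
    speed_schedule: Optional[Sequence[tuple[float, float]]] = None
    speed_range: tuple[float, float] = (2.4, 4.2)
    speed_segment_s: float = 15.0
    n_runners: int = 15
    n_outdoor: int = 5

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def generate_runner(seed: int) -> RunnerProfile:
    """Draw a runner profile from documented parameter ranges.

    Deterministic given ``seed``.  Ranges: mass U(55, 90) kg, cadence
    U(155, 180) steps/min, duty factor U(0.32, 0.40), lobe gains
    U(3.5, 6.0) %BW/(m/s); style factors U(0.85, 1.15) per segment.
    """
    rng = np.random.default_rng(seed)
    style = {
        "thigh_scale": rng.uniform(0.85, 1.15),
        "shank_scale": rng.uniform(0.85, 1.15),
        "foot_scale": rng.uniform(0.85, 1.15),
        "pelvis_scale": rng.uniform(0.85, 1.15),
        "thigh_offset": rng.uniform(-3.0, 3.0),
        "shank_offset": rng.uniform(-3.0, 3.0),
        "foot_offset": rng.uniform(-3.0, 3.0),
        "phase": rng.uniform(-0.3, 0.3),
    }
    return RunnerProfile(
        runner_id=f"R{seed:04d}",
        mass=rng.uniform(55.0, 90.0),
        cadence_base=rng.uniform(155.0, 180.0),
        duty_factor=rng.uniform(0.32, 0.40),
        braking_gain=rng.uniform(3.5, 6.0),
        propulsion_gain=rng.uniform(3.5, 6.0),
        style_offsets=style,
    )


def _speed_schedule(cfg: SimConfig, rng: np.random.Generator):
    if cfg.speed_schedule is not None:
        sched = sorted((float(t), float(v)) for t, v in cfg.speed_schedule)
        if not sched or sched[0][0] > 0:
            sched = [(0.0, sched[0][1] if sched else 3.0)] + sched
        return sched
    lo, hi = cfg.speed_range
    times = np.arange(0.0, cfg.duration, cfg.speed_segment_s)
    return [(float(t), float(rng.uniform(lo, hi))) for t in times]


def _speed_at(schedule, t: np.ndarray | float) -> np.ndarray:
    starts = np.array([s for s, _ in schedule])
    vals = np.array([v for _, v in schedule])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(vals) - 1)
    return vals[idx]


def _ap_force_bw(t: np.ndarray, ic: np.ndarray, to: np.ndarray,
                 amp_brake: np.ndarray, amp_prop: np.ndarray) -> np.ndarray:
    """Evaluate the two-lobe AP-GRF (%BW) at times ``t`` given stance lists."""
    out = np.zeros_like(t)
    for i in range(len(ic)):
        s = to[i] - ic[i]
        tb = BRAKING_FRACTION * s
        tp = s - tb
        rel = t - ic[i]
        m_brake = (rel >= 0) & (rel < tb)
        m_prop = (rel >= tb) & (rel < s)
        out[m_brake] += -amp_brake[i] * np.sin(np.pi * rel[m_brake] / tb)
        out[m_prop] += amp_prop[i] * np.sin(np.pi * (rel[m_prop] - tb) / tp)
    return out


def generate_session(profile: RunnerProfile, shift: SettingShift,
                     cfg: SimConfig) -> tuple[SensorSession, GroundTruth]:
    """Generate one synthetic recording plus its hidden ground truth.

    Deterministic given ``cfg.seed``.  Raises ``ValueError`` if the duration
    is too short to contain one full stride.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    stride_period = 2.0 * 60.0 / profile.cadence_base  # unilateral

    if cfg.duration < 0.3 + stride_period:
        raise ValueError("duration too short for one full stride")

    schedule = _speed_schedule(cfg, rng)

    # --- stride timeline (small per-stride period jitter) ------------------
    starts, periods = [], []
    t = 0.3
    while True:
        p = stride_period * (1.0 + rng.uniform(-0.02, 0.02))
        if t + p > cfg.duration:
            break
        starts.append(t)
        periods.append(p)
        t += p
    starts = np.asarray(starts)
    periods = np.asarray(periods)
    ic_t = starts
    to_t = starts + profile.duty_factor * periods
    stance_speed = _speed_at(schedule, ic_t)

    amp_brake = profile.braking_gain * stance_speed
    amp_prop = profile.propulsion_gain * stance_speed * shift.propulsion_shift

    # --- continuous gait phase (stride index + fraction) -------------------
    t_imu = np.arange(int(round(cfg.duration * fs))) / fs
    idx = np.clip(np.searchsorted(starts, t_imu, side="right") - 1, 0, len(starts) - 1)
    phase = idx + (t_imu - starts[idx]) / periods[idx]
    phi = 2.0 * np.pi * phase + profile.style_offsets.get("phase", 0.0)

    v_frame = _speed_at(schedule, t_imu)
    v_smooth = gaussian_filter1d(v_frame, sigma=0.5 * fs, mode="nearest")

    so = profile.style_offsets

    # --- sagittal angles (deg) ---------------------------------------------
    a_th = (10.0 + 2.5 * v_smooth) * so.get("thigh_scale", 1.0)
    a_sh = (_SHANK_ANGLE_PER_GAIN * profile.braking_gain * v_smooth
            * so.get("shank_scale", 1.0))
    a_ft = (_FOOT_ANGLE_PER_GAIN * profile.propulsion_gain * v_smooth
            * so.get("foot_scale", 1.0))
    angles = {
        "thigh": so.get("thigh_offset", 0.0) + a_th * np.sin(phi + _PHASE["thigh"]),
        "shank": so.get("shank_offset", 0.0) + a_sh * np.sin(phi + _PHASE["shank"]),
        "foot": (so.get("foot_offset", 0.0) + shift.foot_angle_shift
                 + a_ft * np.sin(phi + _PHASE["foot"])),
        "pelvis": 3.0 * so.get("pelvis_scale", 1.0) * np.sin(2 * phi + _PHASE["pelvis"]),
    }

    # Kinematic AP acceleration pattern: mirrors the force lobes but WITHOUT
    # the setting's propulsion shift -- the constructed domain shift.
    amp_prop_kin = profile.propulsion_gain * stance_speed
    lin_shape = _ap_force_bw(t_imu, ic_t, to_t, amp_brake, amp_prop_kin)

    # Impact transient at initial contact (axial shock).
    impact = np.zeros_like(t_imu)
    for i, ti in enumerate(ic_t):
        rel = t_imu - ti
        m = (rel >= 0) & (rel < 0.1)
        impact[m] += (stance_speed[i] / 3.0) * np.exp(-rel[m] / _IMPACT_TAU_S) \
            * np.sin(2 * np.pi * _IMPACT_FREQ_HZ * rel[m])

    sd_acc = profile.noise_sd.get("acc", 0.0) + shift.extra_noise_sd.get("acc", 0.0)
    sd_gyro = profile.noise_sd.get("gyro", 0.0) + shift.extra_noise_sd.get("gyro", 0.0)
    sd_ang = profile.noise_sd.get("angle", 0.0) + shift.extra_noise_sd.get("angle", 0.0)

    g = STANDARD_GRAVITY
    data = {}
    clean_angles = {}
    for seg in ("pelvis", "thigh", "shank", "foot"):
        theta = angles[seg]
        clean_angles[seg] = theta
        th_rad = np.deg2rad(theta)
        lin_x = _LIN_ACC_SCALE[seg] * lin_shape
        acc_x = g * np.sin(th_rad) + lin_x
        acc_z = g * np.cos(th_rad) + _IMPACT_AMP[seg] * impact
        acc_y = 0.3 * np.sin(phi + _PHASE[seg] + 0.7)
        gyro_y = np.gradient(theta) * fs
        gyro_x = 15.0 * so.get(f"{seg}_scale", 1.0) * np.sin(2 * phi + _PHASE[seg] + 1.3)
        gyro_z = 10.0 * np.sin(phi + _PHASE[seg] + 2.4)
        data[f"{seg}_acc_x"] = acc_x + rng.normal(0, sd_acc, t_imu.shape)
        data[f"{seg}_acc_y"] = acc_y + rng.normal(0, sd_acc, t_imu.shape)
        data[f"{seg}_acc_z"] = acc_z + rng.normal(0, sd_acc, t_imu.shape)
        data[f"{seg}_gyro_x"] = gyro_x + rng.normal(0, sd_gyro, t_imu.shape)
        data[f"{seg}_gyro_y"] = gyro_y + rng.normal(0, sd_gyro, t_imu.shape)
        data[f"{seg}_gyro_z"] = gyro_z + rng.normal(0, sd_gyro, t_imu.shape)
    for seg in ("thigh", "shank", "foot"):
        data[f"angle_{seg}"] = clean_angles[seg] + rng.normal(0, sd_ang, t_imu.shape)

    channels = pd.DataFrame(data, columns=all_channel_names())

    # --- truth -------------------------------------------------------------
    ap_truth_bw = _ap_force_bw(t_imu, ic_t, to_t, amp_brake, amp_prop)
    ic_frames = np.ceil(ic_t * fs - 1e-9).astype(int)
    to_frames = np.ceil(to_t * fs - 1e-9).astype(int)
    tb = BRAKING_FRACTION * (to_t - ic_t)
    tp = (to_t - ic_t) - tb
    truth = GroundTruth(
        ap_grf_bw=ap_truth_bw,
        ic_frames=ic_frames,
        to_frames=to_frames,
        stance_speeds=stance_speed,
        braking_impulses=-2.0 * amp_brake * tb / np.pi,
        propulsion_impulses=2.0 * amp_prop * tp / np.pi,
        ic_times_s=ic_t,
        to_times_s=to_t,
        angle_truth=pd.DataFrame({f"angle_{s}": clean_angles[s]
                                  for s in ("thigh", "shank", "foot")}),
    )

    # --- force plates (own rate, newtons) ----------------------------------
    expose_force = shift.setting in ("TM-FP", "OG-FP")
    fv = fap = None
    force_rate = None
    if expose_force:
        t_force = np.arange(int(round(cfg.duration * cfg.force_rate))) / cfg.force_rate
        ap_n = _ap_force_bw(t_force, ic_t, to_t, amp_brake, amp_prop) \
            * profile.bodyweight / 100.0
        vert_bw = np.zeros_like(t_force)
        for i in range(len(ic_t)):
            rel = t_force - ic_t[i]
            m = (rel >= 0) & (rel < to_t[i] - ic_t[i])
            vert_bw[m] += _VERTICAL_PEAK_BW * np.sin(
                np.pi * rel[m] / (to_t[i] - ic_t[i]))
        vert_n = vert_bw * profile.bodyweight
        force_noise = 3.0 * sd_acc / 0.4 if sd_acc > 0 else 0.0
        if force_noise:
            ap_n = ap_n + rng.normal(0, force_noise, ap_n.shape)
            vert_n = vert_n + rng.normal(0, force_noise, vert_n.shape)
        fv, fap, force_rate = vert_n, ap_n, cfg.force_rate

    session = SensorSession(
        participant_id=profile.runner_id,
        setting=shift.setting,
        frame_rate=fs,
        channels=channels,
        bodyweight=profile.bodyweight,
        speed_trace=v_frame,
        force_vertical=fv,
        force_ap=fap,
        force_rate=force_rate,
    )
    return session, truth


@dataclass
class SyntheticDataset:
    """A collection of sessions across runners and settings, plus truths."""

    runners: list[RunnerProfile]
    sessions: dict            # (runner_id, setting) -> SensorSession
    truths: dict              # (runner_id, setting) -> GroundTruth
    manifest: pd.DataFrame

    @property
    def runner_ids(self) -> list[str]:
        return [r.runner_id for r in self.runners]

    def session(self, runner_id: str, setting: str) -> SensorSession:
        return self.sessions[(runner_id, setting)]

    def truth(self, runner_id: str, setting: str) -> GroundTruth:
        """Evaluation-only access to hidden truth (available for all settings)."""
        return self.truths[(runner_id, setting)]

    def loocv_partitions(self):
        """Yield (test_runner_id, train_runner_ids) with each runner held out once."""
        ids = self.runner_ids
        for rid in ids:
            yield rid, [r for r in ids if r != rid]


def make_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Build the full study-design dataset.

    Every runner gets a treadmill (TM-FP) and an overground (OG-FP) session;
    the first ``cfg.n_outdoor`` runners additionally get an outdoor (OUT)
    session whose force truth is withheld from the session object (but kept
    in the truth table for evaluation).  Deterministic given ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    runner_seeds = root.generate_state(cfg.n_runners)
    runners = [generate_runner(int(s) % (2**31)) for s in runner_seeds]

    shifts = {
        "TM-FP": SettingShift.treadmill(),
        "OG-FP": SettingShift.overground(),
        "OUT": SettingShift.outdoor(),
    }
    sessions, truths, rows = {}, {}, []
    session_seeds = iter(root.spawn(1)[0].generate_state(3 * cfg.n_runners))
    for i, runner in enumerate(runners):
        settings = ["TM-FP", "OG-FP"] + (["OUT"] if i < cfg.n_outdoor else [])
        for setting in settings:
            s_seed = int(next(session_seeds)) % (2**31)
            scfg = SimConfig(seed=s_seed, duration=cfg.duration,
                             sample_rate=cfg.sample_rate,
                             force_rate=cfg.force_rate,
                             speed_schedule=cfg.speed_schedule,
                             speed_range=cfg.speed_range,
                             speed_segment_s=cfg.speed_segment_s)
            sess, truth = generate_session(runner, shifts[setting], scfg)
            sessions[(runner.runner_id, setting)] = sess
            truths[(runner.runner_id, setting)] = truth
            rows.append({
                "runner_id": runner.runner_id,
                "setting": setting,
                "seed": s_seed,
                "n_frames": sess.n_frames,
                "n_stances": truth.n_stances,
                "force_available": sess.has_force,
            })
    manifest = pd.DataFrame(rows)
    return SyntheticDataset(runners=runners, sessions=sessions,
                            truths=truths, manifest=manifest)
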