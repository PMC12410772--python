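"""Filtering, resampling, normalization, angles and synchronization."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.signal import periodogram

import runkinetics as rk
from runkinetics.session import STANDARD_GRAVITY
from runkinetics.signal_prep import (
    FilterSpec,
    apply_normalization,
    butter_filter,
    condition_session,
    default_groups,
    extract_sagittal_angle,
    fit_normalization,
    force_to_percent_bw,
    resample_force_to_imu,
    sync_by_cross_correlation,
)
from runkinetics.segmentation import detect_stance_from_force

FS = 120.0
SPEC50 = FilterSpec(cutoff_hz=50.0)


class TestButterFilter:
    def test_dc_gain_is_one(self):
        x = np.full(200, 3.7)
        assert np.allclose(butter_filter(x, SPEC50, FS), 3.7)

    def test_zero_phase_preserves_symmetry(self):
        t = np.arange(301)
        pulse = np.exp(-0.5 * ((t - 150) / 10.0) ** 2)
        y = butter_filter(pulse, SPEC50, FS)
        assert np.allclose(y, y[::-1], atol=1e-10)

    def test_highband_power_attenuated(self):
        # Forward-backward 4th-order Butterworth has power transfer
        # |H|^4 = (1+(f/fc)^8)^-2: ~0.10 at 55 Hz, ~0.036 at 60 Hz, so the
        # 55-60 Hz band of white noise must lose >= 90% of its power (and
        # the full 50-60 Hz band, which includes the transition edge, >= 75%).
        rng = np.random.default_rng(0)
        x = rng.normal(size=2 ** 15)
        y = butter_filter(x, SPEC50, FS)
        f, pxx = periodogram(x, fs=FS)
        _, pyy = periodogram(y, fs=FS)
        band = f >= 55.0
        assert pyy[band].sum() / pxx[band].sum() < 0.10
        edge = f >= 50.0
        assert pyy[edge].sum() / pxx[edge].sum() < 0.25

    def test_reverse_commutes_away_from_edges(self):
        # Zero-phase symmetry is exact for the ideal filter; the finite
        # reflect padding leaves a boundary transient, so the identity is
        # checked outside the first/last 60 samples.
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        a = butter_filter(x, SPEC50, FS)[::-1]
        b = butter_filter(x[::-1], SPEC50, FS)
        assert np.allclose(a[60:-60], b[60:-60], atol=1e-6)
        assert np.max(np.abs(a - b)) < 0.05

    def test_too_short_or_bad_cutoff_raises(self):
        with pytest.raises(ValueError):
            butter_filter(np.zeros(10), SPEC50, FS)
        with pytest.raises(ValueError):
            butter_filter(np.zeros(100), FilterSpec(cutoff_hz=70.0), FS)


class TestResample:
    def test_constant(self):
        out = resample_force_to_imu(np.full(2000, 5.0), 2000.0, 120, 120.0)
        assert np.allclose(out, 5.0)

    def test_linear_ramp_exact(self):
        force = np.arange(4000) / 2000.0          # 1 N/s ramp
        out = resample_force_to_imu(force, 2000.0, 240, 120.0)
        assert np.allclose(out, np.arange(240) / 120.0, atol=1e-12)

    def test_sinusoid_tracked_closely(self):
        t_force = np.arange(4000) / 2000.0
        force = np.sin(2 * np.pi * 10.0 * t_force)
        out = resample_force_to_imu(force, 2000.0, 230, 120.0)
        t_imu = np.arange(230) / 120.0
        assert np.max(np.abs(out - np.sin(2 * np.pi * 10.0 * t_imu))) < 1e-6


class TestPercentBodyweight:
    def test_unit_cases(self):
        assert force_to_percent_bw(np.array([700.0]), 700.0)[0] == 100.0
        assert force_to_percent_bw(np.array([0.0]), 700.0)[0] == 0.0

    def test_mass_based_conversion(self):
        out = force_to_percent_bw(np.array([490.3325]), mass_kg=100.0)
        assert np.isclose(out[0], 50.0)

    def test_requires_a_weight(self):
        with pytest.raises(ValueError):
            force_to_percent_bw(np.array([1.0]))


class TestSagittalAngle:
    def test_static_sensor_reads_zero(self):
        n = 1200
        acc = np.tile([0.0, 0.0, STANDARD_GRAVITY], (n, 1))
        gyro = np.zeros((n, 3))
        ang = extract_sagittal_angle(acc, gyro, FS)
        assert np.max(np.abs(ang)) < 1e-6

    def test_constant_rotation_gives_ramp(self):
        n, omega = 720, 25.0          # 6 s at 25 deg/s
        t = np.arange(n) / FS
        theta = omega * t
        rad = np.deg2rad(theta)
        acc = np.column_stack([STANDARD_GRAVITY * np.sin(rad),
                               np.zeros(n),
                               STANDARD_GRAVITY * np.cos(rad)])
        gyro = np.column_stack([np.zeros(n), np.full(n, omega), np.zeros(n)])
        ang = extract_sagittal_angle(acc, gyro, FS)
        gyro_int = np.concatenate(
            [[0.0], cumulative_trapezoid(gyro[:, 1], dx=1 / FS)])
        assert np.max(np.abs(ang - gyro_int)) < 0.5
        assert np.max(np.abs(ang - theta)) < 0.5

    def test_recovers_generator_angle(self, clean_session):
        session, truth = clean_session
        for seg in ("thigh", "shank", "foot"):
            acc = session.channels[[f"{seg}_acc_{a}" for a in "xyz"]].to_numpy()
            gyro = session.channels[[f"{seg}_gyro_{a}" for a in "xyz"]].to_numpy()
            ang = extract_sagittal_angle(acc, gyro, session.frame_rate)
            err = ang - truth.angle_truth[f"angle_{seg}"].to_numpy()
            rmse = np.sqrt(np.mean(err[120:-120] ** 2))
            assert rmse < 1.0, f"{seg}: RMSE {rmse:.2f} deg"

    def test_degenerate_gravity_raises(self):
        with pytest.raises(ValueError):
            extract_sagittal_angle(np.zeros((600, 3)), np.zeros((600, 3)), FS)

    def test_global_frame_transform_cancels_tilt(self):
        from runkinetics.signal_prep import acceleration_to_global
        theta = np.linspace(-40.0, 40.0, 100)
        rad = np.deg2rad(theta)
        acc = np.column_stack([STANDARD_GRAVITY * np.sin(rad),
                               np.zeros(100),
                               STANDARD_GRAVITY * np.cos(rad)])
        out = acceleration_to_global(acc, theta)
        assert np.allclose(out[:, 0], 0.0, atol=1e-12)
        assert np.allclose(out[:, 2], STANDARD_GRAVITY)


class TestSync:
    @staticmethod
    def _reference(seed=0, n=600):
        rng = np.random.default_rng(seed)
        return butter_filter(rng.normal(size=n), FilterSpec(cutoff_hz=5.0), FS)

    def test_identical_series_lag_zero(self):
        ref = self._reference()
        assert sync_by_cross_correlation(ref, ref) == 0

    def test_known_delay_recovered(self):
        ref = self._reference(1)
        delayed = np.concatenate([np.zeros(12), ref[:-12]])
        assert sync_by_cross_correlation(ref, delayed) == 12

    def test_delay_under_noise_within_one_frame(self):
        hits = []
        for seed in range(100):
            ref = self._reference(seed)
            delayed = np.concatenate([np.zeros(12), ref[:-12]])
            noise_sd = ref.std() / np.sqrt(10.0)     # SNR 10 in power
            rng = np.random.default_rng(1000 + seed)
            noisy = delayed + rng.normal(0, noise_sd, delayed.shape)
            hits.append(abs(sync_by_cross_correlation(ref, noisy) - 12) <= 1)
        assert np.mean(hits) == 1.0


class TestNormalization:
    def test_affine_map_example(self):
        frame = pd.DataFrame({"a": [-2.0, 0.0, 2.0, 4.0]})
        spec = fit_normalization(frame, groups={"g": ["a"]})
        out = apply_normalization(frame, spec)
        assert np.allclose(out["a"], [0.0, 1 / 3, 2 / 3, 1.0])

    def test_shared_group_preserves_relative_magnitude(self):
        t = np.linspace(0, 2 * np.pi, 100)
        frame = pd.DataFrame({"x": 2.0 * np.sin(t), "y": 1.0 * np.sin(t)})
        spec = fit_normalization(frame, groups={"g": ["x", "y"]})
        out = apply_normalization(frame, spec)
        centered = out - out.mean()
        ratio = centered["x"].max() / centered["y"].max()
        assert np.isclose(ratio, 2.0)

    def test_outside_training_range_not_clipped(self):
        train = pd.DataFrame({"a": [0.0, 1.0]})
        spec = fit_normalization(train, groups={"g": ["a"]})
        out = apply_normalization(pd.DataFrame({"a": [2.0, -1.0]}), spec)
        assert out["a"].iloc[0] == 2.0 and out["a"].iloc[1] == -1.0

    def test_training_extrema_map_to_unit_interval(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        spec = fit_normalization(frame, groups={"g1": ["a", "b"], "g2": ["c"]})
        out = apply_normalization(frame, spec)
        assert np.isclose(out[["a", "b"]].to_numpy().min(), 0.0)
        assert np.isclose(out[["a", "b"]].to_numpy().max(), 1.0)
        assert np.isclose(out["c"].min(), 0.0) and np.isclose(out["c"].max(), 1.0)

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError):
            fit_normalization(pd.DataFrame({"a": [1.0, 1.0]}),
                              groups={"g": ["a"]})

    def test_default_groups_cover_all_channels(self):
        names = rk.all_channel_names()
        groups = default_groups(names)
        members = [c for g in groups.values() for c in g]
        assert sorted(members) == sorted(names)
        assert len(groups["pelvis_acc"]) == 3
        assert groups["angle_foot"] == ["angle_foot"]

    def test_spec_roundtrips_through_json(self, tmp_path):
        frame = pd.DataFrame({"a": [0.0, 2.0], "b": [1.0, 3.0]})
        spec = fit_normalization(frame, groups={"g": ["a", "b"]})
        spec.to_json(tmp_path / "norm.json")
        loaded = rk.NormalizationSpec.from_json(tmp_path / "norm.json")
        assert loaded.ranges == {"g": (0.0, 3.0)}


class TestConditionSession:
    def test_stance_timing_unchanged_by_conditioning(self, clean_session):
        session, _ = clean_session
        cond = condition_session(session)
        raw_resampled = resample_force_to_imu(
            session.force_vertical, session.force_rate,
            session.n_frames, session.frame_rate)
        ev_raw = detect_stance_from_force(raw_resampled)
        ev_cond = detect_stance_from_force(cond.force_vertical)
        assert ev_raw.n_stances == ev_cond.n_stances
        assert np.max(np.abs(ev_raw.ic_frames - ev_cond.ic_frames)) <= 1
        assert np.max(np.abs(ev_raw.to_frames - ev_cond.to_frames)) <= 1
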