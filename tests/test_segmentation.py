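"""Stance extraction, window extension, sub-sequences, event detection."""

import numpy as np
import pytest

from runkinetics.segmentation import (
    GaitEvents,
    SwingRule,
    detect_gait_events_from_prediction,
    detect_gait_events_oracle,
    detect_stance_from_force,
    detect_swing_runs,
    event_rmse,
    extend_window,
    make_subsequences,
    stitch_predictions,
)
from runkinetics.experiments import prepare_session


class TestForceThreshold:
    def test_worked_example(self):
        force = np.array([0, 10, 25, 400, 300, 25, 10, 0], dtype=float)
        ev = detect_stance_from_force(force, threshold_n=20.0)
        assert ev.n_stances == 1
        assert ev.ic_frames[0] == 2 and ev.to_frames[0] == 6

    def test_all_zero_gives_no_stances(self):
        assert detect_stance_from_force(np.zeros(100)).n_stances == 0

    def test_matches_generator_truth_noise_free(self, clean_session):
        session, truth = clean_session
        prep = prepare_session(session)
        ev = prep.events
        assert ev.n_stances == truth.n_stances
        assert np.max(np.abs(ev.ic_frames - truth.ic_frames)) <= 1
        assert np.max(np.abs(ev.to_frames - truth.to_frames)) <= 1


class TestWindowExtension:
    def test_interior_window_arithmetic(self):
        ev = GaitEvents([40], [90])
        (w,) = extend_window(ev, n_frames=200)
        assert (w.window_start, w.window_end) == (11, 119)
        assert not w.clipped

    def test_boundary_window_clipped_and_flagged(self):
        ev = GaitEvents([10], [50])
        (w,) = extend_window(ev, n_frames=200)
        assert (w.window_start, w.window_end) == (0, 79)
        assert w.clipped

    def test_pad_matches_published_duration(self):
        assert abs(29 / 120.0 - 0.242) < 5e-4


class TestSubSequences:
    def test_count_at_hop_one(self):
        subs = make_subsequences(np.zeros((100, 3)))
        assert len(subs) == 79

    def test_single_window_midpoint(self):
        target = np.arange(22.0)
        subs = make_subsequences(np.zeros((22, 2)), target)
        assert len(subs) == 1
        assert subs[0].t_mid == 11 and subs[0].y == 11.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            make_subsequences(np.zeros((21, 2)))

    def test_roundtrip_identity_on_target_valued_series(self, clean_session):
        """detect -> extend -> sub-sequences -> stitch reproduces the input."""
        _, truth = clean_session
        target = truth.ap_grf_bw
        subs = make_subsequences(target[:, None], target)
        wave = stitch_predictions(np.array([s.y for s in subs]),
                                  np.array([s.t_mid for s in subs]),
                                  len(target))
        covered = ~np.isnan(wave)
        assert covered.sum() == len(target) - 21
        assert np.array_equal(wave[covered], target[11:len(target) - 10])
        assert np.all(np.isnan(wave[:11])) and np.all(np.isnan(wave[-10:]))


class TestStitch:
    def test_hop_two_fills_gaps_linearly(self):
        target = np.linspace(0.0, 10.0, 60)
        subs = make_subsequences(target[:, None], target, hop=2)
        wave = stitch_predictions(np.array([s.y for s in subs]),
                                  np.array([s.t_mid for s in subs]), 60)
        covered = ~np.isnan(wave)
        assert np.allclose(wave[covered], target[covered])


class TestPredictionEvents:
    def test_worked_example(self):
        wave = np.concatenate([np.full(30, 15.0), np.zeros(20),
                               np.full(30, -10.0)])
        # one swing run over the zero plateau: TO at its start, IC after it
        runs = detect_swing_runs(wave)
        assert runs == [(30, 50)]
        to, ic = runs[0][0], runs[0][1]
        assert to == 30 and ic == 50
        # a lone swing bounds no complete stance on either side
        assert detect_gait_events_from_prediction(wave).n_stances == 0
        # with swing phases around, the stances pair up
        wave2 = np.concatenate([np.zeros(20), np.full(30, 15.0), np.zeros(20),
                                np.full(30, -10.0), np.zeros(20)])
        ev2 = detect_gait_events_from_prediction(wave2, frame_rate=120.0)
        assert list(ev2.ic_frames) == [20, 70]
        # signed slope: after the negative plateau the first zero frame is
        # reached by a +10 jump and does not qualify, so that TO is one late
        assert list(ev2.to_frames) == [50, 101]

    def test_constant_zero_is_all_swing(self):
        ev = detect_gait_events_from_prediction(np.zeros(100))
        assert ev.n_stances == 0

    def test_short_dip_is_not_a_swing(self):
        stance = np.full(60, 12.0)
        stance[30:34] = 0.2             # 4-frame near-zero dip: below min_run
        wave = np.concatenate([np.zeros(20), stance, np.zeros(20)])
        ev = detect_gait_events_from_prediction(wave, frame_rate=120.0)
        assert ev.n_stances == 1
        assert ev.ic_frames[0] == 20 and ev.to_frames[0] == 80

    def test_nan_frames_split_candidate_runs(self):
        wave = np.concatenate([np.zeros(20), np.full(30, 12.0), np.zeros(7)])
        wave[54] = np.nan               # inside the trailing near-zero run
        ev = detect_gait_events_from_prediction(wave, frame_rate=120.0)
        assert ev.n_stances == 0        # trailing run split below min_run

    def test_truth_events_recovered_and_oracle_agrees(self, clean_session):
        _, truth = clean_session
        wave = truth.ap_grf_bw
        ev = detect_gait_events_from_prediction(wave, frame_rate=120.0)
        oracle = detect_gait_events_oracle(wave, frame_rate=120.0)
        assert np.array_equal(ev.ic_frames, oracle.ic_frames)
        assert np.array_equal(ev.to_frames, oracle.to_frames)
        assert ev.n_stances == truth.n_stances
        assert np.max(np.abs(ev.ic_frames - truth.ic_frames)) <= 2
        assert np.max(np.abs(ev.to_frames - truth.to_frames)) <= 2


class TestPersistence:
    def test_events_csv_roundtrip(self, tmp_path):
        from runkinetics.segmentation import events_from_csv, events_to_csv
        ev = GaitEvents([10, 100], [40, 140])
        events_to_csv(ev, tmp_path / "ev.csv", 120.0)
        loaded = events_from_csv(tmp_path / "ev.csv")
        assert np.array_equal(loaded.ic_frames, ev.ic_frames)
        assert np.array_equal(loaded.to_frames, ev.to_frames)

    def test_window_container_roundtrip(self, tmp_path, clean_session):
        from runkinetics.segmentation import load_windows, save_windows
        session, _ = clean_session
        prep = prepare_session(session)
        save_windows(prep.windows[:3], tmp_path / "w.npz")
        loaded = load_windows(tmp_path / "w.npz")
        assert len(loaded) == 3
        for a, b in zip(loaded, prep.windows[:3]):
            assert a.window_start == b.window_start
            assert np.allclose(a.inputs, b.inputs)
            assert np.allclose(a.target, b.target)
            assert list(a.channel_names) == list(b.channel_names)


class TestEventRmse:
    def test_identical_events_zero_error(self):
        ev = GaitEvents(np.arange(0, 500, 100), np.arange(40, 540, 100))
        out = event_rmse(ev, ev, 120.0)
        assert out["ic_rmse_s"] == 0.0 and out["to_rmse_s"] == 0.0
        assert out["ic_unmatched"] == 0

    def test_uniform_shift_scores_shift(self):
        truth = GaitEvents(np.arange(0, 1000, 100), np.arange(40, 1040, 100))
        pred = GaitEvents(truth.ic_frames + 6, truth.to_frames + 6)
        out = event_rmse(pred, truth, 120.0)
        assert np.isclose(out["ic_rmse_s"], 0.05)
        assert np.isclose(out["to_rmse_s"], 0.05)

    def test_empty_prediction_raises(self):
        truth = GaitEvents([10], [40])
        empty = GaitEvents(np.empty(0, int), np.empty(0, int))
        with pytest.raises(ValueError):
            event_rmse(empty, truth, 120.0)
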