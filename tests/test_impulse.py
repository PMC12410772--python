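"""Impulse integration, speed binning, weighted fits and comparisons."""

import numpy as np
import pytest


from runkinetics.impulse import (
    COMPARISON_GRID,
    ImpulsePoint,
    LinearFit,
    SpeedBin,
    attach_speeds,
    bin_by_speed,
    compare_fits,
    compute_impulses,
    ols_fit,
    speed_impulse_fit,
    weighted_linear_fit,
)
from runkinetics.segmentation import GaitEvents

FS = 120.0


def make_points(speeds, values, metric="propulsion_impulse"):
    pts = []
    for i, (s, v) in enumerate(zip(speeds, values)):
        kw = {"braking_impulse": 0.0, "propulsion_impulse": 0.0}
        kw[metric] = v
        pts.append(ImpulsePoint(stance_id=i, speed=s, **kw))
    return pts


def brute_force_wls(xs, ys, ws):
    """Independent oracle: iteratively refined 2-D grid search of the
    weighted squared loss, parameterized with the weighted-centered
    predictor (level and slope are then orthogonal, so the shrinking
    grid cannot lose the optimum in a diagonal valley)."""
    xbar = np.sum(ws * xs) / np.sum(ws)
    xc = xs - xbar
    c0, b0 = float(np.sum(ws * ys) / np.sum(ws)), 0.0
    rc = rb = 20.0
    for _ in range(16):
        C = np.linspace(c0 - rc, c0 + rc, 21)
        B = np.linspace(b0 - rb, b0 + rb, 21)
        resid = (ys[None, None, :] - C[:, None, None]
                 - B[None, :, None] * xc[None, None, :])
        L = (ws * resid ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(L), L.shape)
        c0, b0 = float(C[i]), float(B[j])
        rc /= 5.0
        rb /= 5.0
    return c0 - b0 * xbar, b0  # intercept, slope


class TestComputeImpulses:
    def test_constant_braking_block(self):
        wave = np.zeros(40)
        wave[:13] = -10.0                       # 0.1 s at constant -10 %BW
        ev = GaitEvents([0], [12])
        (p,) = compute_impulses(wave, ev, FS)
        assert np.isclose(p.braking_impulse, -1.0)
        assert p.propulsion_impulse == 0.0

    def test_half_sine_lobe_close_to_analytic(self):
        dur = 0.12
        n = int(np.floor(dur * FS))             # lobe sampled on the frame grid
        t = np.arange(n + 1) / FS
        wave = np.concatenate([20.0 * np.maximum(np.sin(np.pi * t / dur), 0.0),
                               np.zeros(10)])
        ev = GaitEvents([0], [n])
        (p,) = compute_impulses(wave, ev, FS)
        analytic = 2.0 * 20.0 * dur / np.pi
        assert abs(p.propulsion_impulse - analytic) / analytic < 0.01

    def test_zero_waveform_zero_impulses(self):
        ev = GaitEvents([5], [25])
        (p,) = compute_impulses(np.zeros(40), ev, FS)
        assert p.braking_impulse == 0.0 and p.propulsion_impulse == 0.0

    def test_decomposition_identity(self):
        rng = np.random.default_rng(2)
        wave = rng.normal(scale=10.0, size=200)
        ev = GaitEvents([10, 100], [60, 150])
        full = compute_impulses(wave, ev, FS)
        neg = compute_impulses(np.minimum(wave, 0.0), ev, FS)
        pos = compute_impulses(np.maximum(wave, 0.0), ev, FS)
        for f, n_, p_ in zip(full, neg, pos):
            assert np.isclose(f.braking_impulse,
                              n_.braking_impulse + p_.braking_impulse)
            assert np.isclose(f.propulsion_impulse,
                              n_.propulsion_impulse + p_.propulsion_impulse)

    def test_speeds_attached_from_trace(self):
        wave = np.ones(100)
        ev = GaitEvents([10, 60], [30, 80])
        trace = np.concatenate([np.full(50, 3.0), np.full(50, 4.0)])
        pts = attach_speeds(compute_impulses(wave, ev, FS), ev, trace)
        assert pts[0].speed == 3.0 and pts[1].speed == 4.0


class TestSpeedBinning:
    def test_sparse_bins_discarded(self):
        pts = make_points([2.05, 2.05, 2.05, 2.61, 2.61], [1, 1, 1, 2, 2])
        bins = bin_by_speed(pts)
        assert len(bins) == 1
        assert bins[0].interval == (2.0, 2.1)
        assert len(bins[0].members) == 3

    def test_top_edge_is_exclusive(self):
        pts = make_points([4.5, 4.5, 4.5], [1, 1, 1])
        assert bin_by_speed(pts) == []

    def test_empty_input(self):
        assert bin_by_speed([]) == []


class TestWeightedFit:
    def test_exact_line_with_equal_weights(self):
        pts = make_points([2.0] * 3 + [3.0] * 3 + [4.0] * 3,
                          [1.0] * 3 + [2.0] * 3 + [3.0] * 3)
        # identical members per bin: variances all hit the floor equally
        bins = [SpeedBin(left=2.0, members=pts[:3]),
                SpeedBin(left=3.0, members=pts[3:6]),
                SpeedBin(left=4.0, members=pts[6:])]
        fit = weighted_linear_fit(bins)
        assert np.isclose(fit.slope, 1.0)
        assert np.isclose(fit.intercept, -1.0)
        assert np.isclose(fit.r_squared, 1.0)

    def test_matches_brute_force_on_heteroscedastic_bins(self):
        rng = np.random.default_rng(7)
        bins, xs, ys, ws = [], [], [], []
        for left, sd in ((2.0, 0.05), (2.7, 0.4), (3.6, 1.1)):
            speeds = left + rng.uniform(0, 0.1, size=6)
            vals = 0.5 + 0.8 * speeds + rng.normal(0, sd, size=6)
            pts = make_points(speeds, vals)
            bins.append(SpeedBin(left=left, members=pts))
            w = 1.0 / np.var(vals, ddof=1)
            xs += list(speeds); ys += list(vals); ws += [w] * 6
        fit = weighted_linear_fit(bins)
        a, b = brute_force_wls(np.array(xs), np.array(ys), np.array(ws))
        assert abs(fit.intercept - a) < 1e-6
        assert abs(fit.slope - b) < 1e-6

    def test_equal_weights_reduce_to_ols(self):
        # bins constructed with identical sample variances -> equal weights
        speeds = np.repeat([2.05, 2.55, 3.05, 3.55], 3)
        spread = np.tile([-0.2, 0.0, 0.2], 4)
        vals = 1.0 + 0.5 * speeds + spread
        pts = make_points(speeds, vals)
        bins = [SpeedBin(left=l, members=[p for p in pts
                                          if l <= p.speed < l + 0.1])
                for l in (2.0, 2.5, 3.0, 3.5)]
        wls = weighted_linear_fit(bins)
        ols = ols_fit(pts)
        assert np.isclose(wls.slope, ols.slope, atol=1e-10)
        assert np.isclose(wls.intercept, ols.intercept, atol=1e-10)
        assert np.isclose(wls.r_squared, ols.r_squared, atol=1e-10)

    def test_single_bin_raises(self):
        pts = make_points([2.05, 2.06, 2.07], [1, 1, 1])
        with pytest.raises(ValueError):
            weighted_linear_fit([SpeedBin(left=2.0, members=pts)])

    def test_speed_impulse_fit_errors_without_bins(self):
        pts = make_points([5.0, 5.1, 5.2], [1, 1, 1])  # all out of range
        with pytest.raises(ValueError, match="m/s"):
            speed_impulse_fit(pts, "propulsion_impulse")


class TestCompareFits:
    def test_identical_fits_zero_rmse(self):
        f = LinearFit(slope=0.5, intercept=0.1, r_squared=0.9)
        assert compare_fits(f, f).rmse == 0.0

    def test_constant_offset(self):
        a = LinearFit(slope=0.5, intercept=0.1, r_squared=0.9)
        b = LinearFit(slope=0.5, intercept=0.2, r_squared=0.9)
        assert np.isclose(compare_fits(a, b).rmse, 0.1)

    def test_slope_difference_closed_form(self):
        a = LinearFit(slope=0.6, intercept=0.0, r_squared=1.0)
        b = LinearFit(slope=0.5, intercept=0.0, r_squared=1.0)
        expected = 0.1 * np.sqrt(np.mean(COMPARISON_GRID ** 2))
        assert np.isclose(compare_fits(a, b).rmse, expected)
        assert len(COMPARISON_GRID) == 25
        assert np.isclose(COMPARISON_GRID[0], 2.05)
        assert np.isclose(COMPARISON_GRID[-1], 4.45)
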