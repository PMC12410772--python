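"""Braking/propulsion impulses and speed-binned weighted linear fits.

Where no force plates exist, predictions are validated through the expected
linear relationship between per-stance braking/propulsion impulse and
running speed: stances are binned into 25 speed bins of width 0.1 m/s over
[2.0, 4.5) m/s, bins with fewer than three stances are discarded, a linear
model is fit to the surviving observations with inverse-variance bin
weights (w_i = 1 / sigma_i^2), and the fitted line is compared to the
force-plate reference line by the RMSE of their evaluations on the 25 bin
centers (2.05 ... 4.45 m/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.integrate import simpson

from .segmentation import GaitEvents

log = logging.getLogger(__name__)

SPEED_BIN_WIDTH = 0.1
SPEED_MIN = 2.0
SPEED_MAX = 4.5
N_BINS = 25
MIN_BIN_MEMBERS = 3
#: Variance floor for a degenerate (constant-valued) bin, (%BW.s)^2.
VARIANCE_FLOOR = 1e-8

#: The 25 bin-center speeds used for line comparison (2.05 ... 4.45 m/s).
COMPARISON_GRID = SPEED_MIN + SPEED_BIN_WIDTH * (np.arange(N_BINS) + 0.5)


@dataclass
class ImpulsePoint:
    """Per-stance impulses (%BW.s, signed) with the stance's speed."""

    stance_id: int
    braking_impulse: float      # <= 0 by convention
    propulsion_impulse: float   # >= 0
    speed: float                # m/s
    source: str = "force_plate"


@dataclass
class SpeedBin:
    """One 0.1 m/s speed bin and its member observations."""

    left: float
    members: list = field(default_factory=list)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.left, self.left + SPEED_BIN_WIDTH)

    def values(self, metric: str) -> np.ndarray:
        return np.array([getattr(p, metric) for p in self.members])


@dataclass
class LinearFit:
    """Line impulse = intercept + slope * speed, with weighted R^2."""

    slope: float
    intercept: float
    r_squared: float
    weighted: bool = True
    n_bins: int = 0
    n_points: int = 0

    def predict(self, speeds: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(speeds, dtype=float)


@dataclass
class FitComparison:
    """RMSE between two fitted lines over the 25-point comparison grid."""

    reference: LinearFit
    candidate: LinearFit
    grid: np.ndarray
    rmse: float


def compute_impulses(waveform_bw: np.ndarray, events: GaitEvents,
                     frame_rate: float,
                     source: str = "force_plate") -> list[ImpulsePoint]:
    """Integrate braking/propulsion impulses over each stance.

    Braking is the integral of the negative portion of the AP-GRF over the
    stance, propulsion of the positive portion (Simpson's rule on the
    sampled stance; the decomposition ``impulse(F) = impulse(F-) +
    impulse(F+)`` holds exactly by linearity).  Speeds are filled in by the
    caller; here they default to NaN.
    """
    wave = np.asarray(waveform_bw, dtype=float)
    points = []
    for k, (ic, to) in enumerate(zip(events.ic_frames, events.to_frames)):
        seg = wave[max(ic, 0):min(to + 1, len(wave))]
        seg = np.nan_to_num(seg, nan=0.0)
        if len(seg) < 2:
            continue
        x = np.arange(len(seg)) / frame_rate
        brake = float(simpson(np.minimum(seg, 0.0), x=x))
        prop = float(simpson(np.maximum(seg, 0.0), x=x))
        points.append(ImpulsePoint(stance_id=k, braking_impulse=brake,
                                   propulsion_impulse=prop, speed=np.nan,
                                   source=source))
    return points


def attach_speeds(points: Sequence[ImpulsePoint], events: GaitEvents,
                  speed_trace: np.ndarray) -> list[ImpulsePoint]:
    """Set each point's speed to the mean of the speed trace over its stance."""
    speed_trace = np.asarray(speed_trace, dtype=float)
    for p in points:
        ic = events.ic_frames[p.stance_id]
        to = events.to_frames[p.stance_id]
        p.speed = float(np.mean(speed_trace[max(ic, 0):to]))
    return list(points)


def bin_by_speed(points: Sequence[ImpulsePoint]) -> list[SpeedBin]:
    """Assign stances to the 25 half-open speed bins; drop sparse bins.

    Membership is by ``speed in [left, left + 0.1)``; a speed of exactly
    4.5 m/s falls outside every bin.  Bins with fewer than three members
    are discarded (logged).
    """
    bins = {k: SpeedBin(left=round(SPEED_MIN + k * SPEED_BIN_WIDTH, 10))
            for k in range(N_BINS)}
    dropped_points = 0
    for p in points:
        k = int(np.floor((p.speed - SPEED_MIN) / SPEED_BIN_WIDTH))
        if 0 <= k < N_BINS and p.speed < SPEED_MAX:
            bins[k].members.append(p)
        else:
            dropped_points += 1
    if dropped_points:
        log.info("bin_by_speed: %d stances outside [%.1f, %.1f) m/s",
                 dropped_points, SPEED_MIN, SPEED_MAX)
    kept = []
    for k in range(N_BINS):
        if len(bins[k].members) >= MIN_BIN_MEMBERS:
            kept.append(bins[k])
        elif bins[k].members:
            log.info("bin_by_speed: discarding bin [%.1f, %.1f) with %d stances",
                     *bins[k].interval, len(bins[k].members))
    return kept


def weighted_linear_fit(bins: Sequence[SpeedBin],
                        metric: str = "propulsion_impulse") -> LinearFit:
    """Inverse-variance weighted least squares of impulse on speed.

    Every member observation enters the regression with its bin's weight
    ``w_i = 1 / sigma_i^2`` (bin variance floored at a small epsilon when
    degenerate).  R^2 is the weighted coefficient of determination.
    Raises ``ValueError`` with fewer than two surviving bins.
    """
    if len(bins) < 2:
        raise ValueError(f"need >= 2 surviving speed bins, got {len(bins)}")
    xs, ys, ws = [], [], []
    for b in bins:
        vals = b.values(metric)
        var = float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.0
        if var < VARIANCE_FLOOR:
            log.info("weighted_linear_fit: variance floor hit in bin %s", b.interval)
            var = VARIANCE_FLOOR
        w = 1.0 / var
        for p in b.members:
            xs.append(p.speed)
            ys.append(getattr(p, metric))
            ws.append(w)
    X = sm.add_constant(np.asarray(xs))
    model = sm.WLS(np.asarray(ys), X, weights=np.asarray(ws)).fit()
    return LinearFit(slope=float(model.params[1]),
                     intercept=float(model.params[0]),
                     r_squared=float(model.rsquared),
                     weighted=True, n_bins=len(bins), n_points=len(ys))


def ols_fit(points: Sequence[ImpulsePoint],
            metric: str = "propulsion_impulse") -> LinearFit:
    """Unweighted least squares over raw stance observations."""
    xs = np.array([p.speed for p in points])
    ys = np.array([getattr(p, metric) for p in points])
    model = sm.OLS(ys, sm.add_constant(xs)).fit()
    return LinearFit(slope=float(model.params[1]),
                     intercept=float(model.params[0]),
                     r_squared=float(model.rsquared),
                     weighted=False, n_bins=0, n_points=len(points))


def compare_fits(reference: LinearFit, candidate: LinearFit,
                 grid: Optional[np.ndarray] = None) -> FitComparison:
    """RMSE between two lines evaluated on the 25 bin-center speeds."""
    grid = COMPARISON_GRID if grid is None else np.asarray(grid, dtype=float)
    diff = reference.predict(grid) - candidate.predict(grid)
    return FitComparison(reference=reference, candidate=candidate, grid=grid,
                         rmse=float(np.sqrt(np.mean(diff ** 2))))


def points_to_frame(points: Sequence[ImpulsePoint]):
    """Tidy table of impulse points (one row per stance)."""
    import pandas as pd
    return pd.DataFrame([{
        "stance_id": p.stance_id,
        "speed_m_s": p.speed,
        "braking_impulse_bw_s": p.braking_impulse,
        "propulsion_impulse_bw_s": p.propulsion_impulse,
        "source": p.source,
    } for p in points])


def speed_impulse_fit(points: Sequence[ImpulsePoint],
                      metric: str) -> LinearFit:
    """Convenience: bin then weighted-fit; structured error when impossible."""
    bins = bin_by_speed(points)
    if len(bins) < 2:
        raise ValueError(
            f"no usable speed-impulse fit: {len(bins)} bins with >= "
            f"{MIN_BIN_MEMBERS} stances in [{SPEED_MIN}, {SPEED_MAX}) m/s")
    return weighted_linear_fit(bins, metric=metric)
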