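"""Gait segmentation: stance extraction, windows, sub-sequences, events.

Two segmentation mechanisms coexist in the pipeline:

* **force-threshold stance extraction** for training data with force plates
  (stance = vertical force above 20 N, from initial contact IC to toe off
  TO), followed by extension of each stance by 29 frames (0.242 s at
  120 Hz — the shortest swing phase) on each side so the model sees swing
  context;
* **prediction-based swing detection** for continuous inference without
  force plates: a run of at least five consecutive predictions with
  magnitude <= 0.5 %BW and slope <= 0.25 %BW/frame is a swing phase; its
  start is TO, its end IC.

Sub-sequences of 22 frames slide over each window (hop 1); the model target
is the AP-GRF at the sub-sequence mid-point (0-based index 11), and a
continuous waveform is re-assembled by placing each prediction at its
mid-point frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Window extension on each side of a stance (frames; 29/120 Hz = 0.242 s).
WINDOW_PAD = 29
#: Sub-sequence length in frames and its 0-based mid-point index.
SUBSEQ_LEN = 22
MIDPOINT = 11
#: Frames at the start/end of a series that hop-1 stitching cannot cover.
EDGE_LEAD = MIDPOINT            # 11
EDGE_TAIL = SUBSEQ_LEN - MIDPOINT - 1  # 10

FORCE_THRESHOLD_N = 20.0


@dataclass
class GaitEvents:
    """Ordered initial-contact and toe-off frame indices.

    Stance ``k`` spans frames ``[ic_frames[k], to_frames[k])``; ``source``
    records whether events came from force plates or model predictions.
    """

    ic_frames: np.ndarray
    to_frames: np.ndarray
    source: str = "force"

    def __post_init__(self) -> None:
        self.ic_frames = np.asarray(self.ic_frames, dtype=int)
        self.to_frames = np.asarray(self.to_frames, dtype=int)
        if len(self.ic_frames) != len(self.to_frames):
            raise ValueError("ic/to lists must pair up")
        if np.any(self.to_frames <= self.ic_frames):
            raise ValueError("every stance needs IC < TO")

    @property
    def n_stances(self) -> int:
        return len(self.ic_frames)

    def stance_mask(self, n_frames: int) -> np.ndarray:
        mask = np.zeros(n_frames, dtype=bool)
        for ic, to in zip(self.ic_frames, self.to_frames):
            mask[max(ic, 0):min(to, n_frames)] = True
        return mask


@dataclass
class SwingRule:
    """Prediction-based swing classification thresholds.

    The slope test is signed by default (``y[t] - y[t-1] <= slope_max``):
    a frame reached by a steep *drop* onto the near-zero band still opens a
    swing run, which puts TO at the first near-zero frame.  Set
    ``signed_slope=False`` for an absolute first-difference test.
    """

    magnitude_max: float = 0.5     # %BW
    slope_max: float = 0.25        # %BW per frame (first difference)
    min_run: int = 5               # frames (~40 ms at 120 Hz)
    min_stance_s: float = 0.1      # discard shorter inter-swing slivers
    signed_slope: bool = True


@dataclass
class StanceWindow:
    """A stance phase with its +-29-frame context window.

    ``inputs`` is (frames, channels) over ``[window_start, window_end)``;
    ``target`` the frame-aligned AP-GRF in %BW over the same window.
    ``clipped`` flags windows truncated at the series bounds.
    """

    stance_start: int
    stance_end: int
    window_start: int
    window_end: int
    inputs: Optional[np.ndarray] = None
    target: Optional[np.ndarray] = None
    clipped: bool = False
    channel_names: Optional[Sequence[str]] = None

    @property
    def n_frames(self) -> int:
        return self.window_end - self.window_start


@dataclass
class SubSequence:
    """A 22-frame input slice with a single mid-point target."""

    x: np.ndarray          # (22, channels)
    t_mid: int             # series-global frame index of the mid-point
    y: Optional[float] = None


def detect_stance_from_force(vertical_force_n: np.ndarray,
                             threshold_n: float = FORCE_THRESHOLD_N
                             ) -> GaitEvents:
    """Stances as maximal runs of vertical force above 20 N.

    IC is the first frame of a run, TO the first frame after it.  Runs
    touching the series boundaries are kept (their IC/TO are the boundary).
    """
    force = np.asarray(vertical_force_n, dtype=float)
    above = force > threshold_n
    if not above.any():
        return GaitEvents(np.empty(0, int), np.empty(0, int), source="force")
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(force)]])
    return GaitEvents(starts, ends, source="force")


def extend_window(events: GaitEvents, n_frames: int,
                  pad: int = WINDOW_PAD) -> list[StanceWindow]:
    """Extend each stance by ``pad`` frames on each side, clipping at bounds."""
    windows = []
    for ic, to in zip(events.ic_frames, events.to_frames):
        ws, we = ic - pad, to + pad
        clipped = ws < 0 or we > n_frames
        windows.append(StanceWindow(
            stance_start=ic, stance_end=to,
            window_start=max(ws, 0), window_end=min(we, n_frames),
            clipped=clipped))
    return windows


def fill_window(window: StanceWindow, inputs: np.ndarray,
                target: Optional[np.ndarray] = None,
                channel_names: Optional[Sequence[str]] = None) -> StanceWindow:
    """Attach input (frames, channels) and %BW target slices to a window."""
    window.inputs = inputs[window.window_start:window.window_end]
    if target is not None:
        window.target = np.asarray(target)[window.window_start:window.window_end]
    window.channel_names = channel_names
    return window


def make_subsequences(inputs: np.ndarray,
                      target: Optional[np.ndarray] = None,
                      hop: int = 1,
                      offset: int = 0) -> list[SubSequence]:
    """Slide a 22-frame window over ``inputs`` (frames, channels).

    ``offset`` is added to the stored mid-point index so sub-sequences cut
    from a window retain series-global frame coordinates.  Raises
    ``ValueError`` if fewer than 22 frames are supplied.
    """
    inputs = np.asarray(inputs)
    n = inputs.shape[0]
    if n < SUBSEQ_LEN:
        raise ValueError(f"need at least {SUBSEQ_LEN} frames, got {n}")
    subs = []
    for s in range(0, n - SUBSEQ_LEN + 1, hop):
        t_mid = s + MIDPOINT
        subs.append(SubSequence(
            x=inputs[s:s + SUBSEQ_LEN],
            t_mid=t_mid + offset,
            y=float(target[t_mid]) if target is not None else None))
    return subs


def stitch_predictions(predictions: np.ndarray,
                       t_mid: np.ndarray,
                       n_frames: int,
                       fill_gaps: bool = True) -> np.ndarray:
    """Assemble a waveform from mid-point predictions.

    Frame ``t`` carries the prediction whose mid-point is ``t``; frames no
    sub-sequence covers (the first 11 and last 10 of a hop-1 series, plus
    interior gaps at hop > 1) are NaN.  Interior gaps are linearly
    interpolated when ``fill_gaps`` is true; the leading/trailing edges stay
    NaN as a missing-value marker.
    """
    wave = np.full(n_frames, np.nan)
    t_mid = np.asarray(t_mid, dtype=int)
    wave[t_mid] = predictions
    if fill_gaps and len(t_mid) > 1:
        lo, hi = t_mid.min(), t_mid.max()
        inner = np.arange(lo, hi + 1)
        have = ~np.isnan(wave[inner])
        wave[inner] = np.interp(inner, inner[have], wave[inner][have])
    return wave


def detect_swing_runs(waveform: np.ndarray,
                      rule: SwingRule = SwingRule()) -> list[tuple[int, int]]:
    """Maximal swing runs ``[start, end)`` of a predicted waveform.

    A frame qualifies when ``|y| <= magnitude_max`` and its first difference
    passes the slope test; NaN (missing-value) frames never qualify, so
    they split candidate runs.  Runs shorter than ``min_run`` are dropped.
    A run's start frame is a toe-off, the frame after its end an initial
    contact.
    """
    y = np.asarray(waveform, dtype=float)
    n = len(y)
    slope = np.empty(n)
    slope[0] = 0.0
    slope[1:] = np.diff(y)
    with np.errstate(invalid="ignore"):
        slope_ok = (slope <= rule.slope_max) if rule.signed_slope \
            else (np.abs(slope) <= rule.slope_max)
        ok = (np.abs(y) <= rule.magnitude_max) & slope_ok
    ok &= ~np.isnan(y) & ~np.isnan(slope)

    swings = []
    start = None
    for i in range(n + 1):
        flag = ok[i] if i < n else False
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= rule.min_run:
                swings.append((start, i))  # [start, i)
            start = None
    return swings


def detect_gait_events_from_prediction(waveform: np.ndarray,
                                       rule: SwingRule = SwingRule(),
                                       frame_rate: float = 120.0
                                       ) -> GaitEvents:
    """Swing/stance segmentation of a predicted AP-GRF waveform.

    Swing runs come from :func:`detect_swing_runs`; a run's first frame is
    TO and the frame after its last is IC.  Stances are the intervals
    between consecutive swing phases (so the events pair up as IC < TO);
    stances shorter than ``min_stance_s`` are discarded.
    """
    swings = detect_swing_runs(waveform, rule)
    if not swings:
        return GaitEvents(np.empty(0, int), np.empty(0, int), source="prediction")
    min_stance = int(round(rule.min_stance_s * frame_rate))
    ic, to = [], []
    for (s0, e0), (s1, _) in zip(swings[:-1], swings[1:]):
        # stance between swing ending at e0 and swing starting at s1
        if s1 - e0 >= min_stance:
            ic.append(e0)
            to.append(s1)
    return GaitEvents(np.array(ic, int), np.array(to, int), source="prediction")


def detect_gait_events_oracle(waveform: np.ndarray,
                              rule: SwingRule = SwingRule(),
                              frame_rate: float = 120.0) -> GaitEvents:
    """Exhaustive run-scan reference implementation (test oracle).

    Checks every candidate interval directly against the swing rule instead
    of streaming through the series once.  Quadratic; for validation only.
    """
    y = np.asarray(waveform, dtype=float)
    n = len(y)

    def qualifies(i: int) -> bool:
        if np.isnan(y[i]) or abs(y[i]) > rule.magnitude_max:
            return False
        d = y[i] - y[i - 1] if i > 0 else 0.0
        if np.isnan(d):
            return False
        return d <= rule.slope_max if rule.signed_slope else abs(d) <= rule.slope_max

    swings = []
    i = 0
    while i < n:
        if qualifies(i):
            j = i
            while j < n and qualifies(j):
                j += 1
            if j - i >= rule.min_run:
                swings.append((i, j))
            i = j
        else:
            i += 1
    min_stance = int(round(rule.min_stance_s * frame_rate))
    ic, to = [], []
    for (s0, e0), (s1, _) in zip(swings[:-1], swings[1:]):
        if s1 - e0 >= min_stance:
            ic.append(e0)
            to.append(s1)
    return GaitEvents(np.array(ic, int), np.array(to, int), source="prediction")


def events_to_csv(events: GaitEvents, path, frame_rate: float) -> None:
    """Write events as tidy CSV with columns frame, time_s, type."""
    import pandas as pd
    rows = []
    for ic, to in zip(events.ic_frames, events.to_frames):
        rows.append({"frame": int(ic), "time_s": ic / frame_rate, "type": "IC"})
        rows.append({"frame": int(to), "time_s": to / frame_rate, "type": "TO"})
    pd.DataFrame(rows, columns=["frame", "time_s", "type"]).to_csv(
        path, index=False)


def events_from_csv(path, source: str = "force") -> GaitEvents:
    import pandas as pd
    table = pd.read_csv(path)
    ic = table.loc[table.type == "IC", "frame"].to_numpy()
    to = table.loc[table.type == "TO", "frame"].to_numpy()
    return GaitEvents(ic, to, source=source)


def save_windows(windows: Sequence[StanceWindow], path) -> None:
    """Persist filled windows to one ``.npz`` container with channel names."""
    arrays, meta = {}, []
    for i, w in enumerate(windows):
        arrays[f"inputs_{i}"] = w.inputs
        if w.target is not None:
            arrays[f"target_{i}"] = w.target
        meta.append([w.stance_start, w.stance_end, w.window_start,
                     w.window_end, int(w.clipped)])
    arrays["meta"] = np.asarray(meta, dtype=int)
    arrays["channel_names"] = np.asarray(list(windows[0].channel_names or []),
                                         dtype="U64")
    np.savez(path, **arrays)


def load_windows(path) -> list[StanceWindow]:
    with np.load(path) as data:
        names = [str(c) for c in data["channel_names"]] or None
        out = []
        for i, row in enumerate(data["meta"]):
            out.append(StanceWindow(
                stance_start=int(row[0]), stance_end=int(row[1]),
                window_start=int(row[2]), window_end=int(row[3]),
                clipped=bool(row[4]), inputs=data[f"inputs_{i}"],
                target=data[f"target_{i}"] if f"target_{i}" in data else None,
                channel_names=names))
    return out


def event_rmse(predicted: GaitEvents, truth: GaitEvents,
               frame_rate: float) -> dict:
    """IC/TO timing error (RMSE, seconds) with nearest-event matching.

    Each predicted event is matched to the nearest true event within half
    the median true stride period; unmatched events on either side are
    counted, not scored.  Raises ``ValueError`` on an empty prediction list.
    """
    if predicted.n_stances == 0:
        raise ValueError("no predicted events to score")
    if truth.n_stances == 0:
        raise ValueError("no reference events to score against")
    if truth.n_stances > 1:
        stride = float(np.median(np.diff(truth.ic_frames)))
    else:
        stride = np.inf
    tol = stride / 2.0

    out = {}
    for key, pred, ref in (("ic", predicted.ic_frames, truth.ic_frames),
                           ("to", predicted.to_frames, truth.to_frames)):
        errs, unmatched = [], 0
        for p in pred:
            d = ref - p
            j = np.argmin(np.abs(d))
            if abs(d[j]) <= tol:
                errs.append(d[j] / frame_rate)
            else:
                unmatched += 1
        out[f"{key}_rmse_s"] = float(np.sqrt(np.mean(np.square(errs)))) \
            if errs else np.nan
        out[f"{key}_unmatched"] = unmatched
    out["n_predicted"] = predicted.n_stances
    out["n_truth"] = truth.n_stances
    return out
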