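"""The AP-GRF regressor: training modes, inference, channel subsets.

Three training modes mirror the study design:

* **generalized** — train from scratch on pooled stance windows of many
  runners (treadmill data), 40 epochs, batch 32, 9:1 train/validation split
  over stances;
* **fine_tune** — continue training *all* weights of a generalized
  estimator on a handful of stances from one runner (15 epochs, batch 16,
  four held-out stances as validation);
* **individual** — train from scratch on those same few stances (batch 1).

All modes use the smooth-L1 loss, learning rate 0.001 and AdamW.  Targets
stay in raw %BW (swing = exactly 0); inputs are min-max normalized in
tri-axial groups with ranges learned from the training data only.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .segmentation import MIDPOINT, SUBSEQ_LEN, StanceWindow, stitch_predictions
from .session import SensorSession, all_channel_names, inertial_channel_names
from .signal_prep import NormalizationSpec, default_groups

#: Single-segment channel subsets: 6 inertial channels per sensor plus the
#: segment's sagittal angle for thigh/shank/foot (pelvis has no angle).
_SEGMENT_SETS = ("foot", "shank", "thigh", "pelvis", "all")


def select_channels(segment: str = "all") -> list[str]:
    """Model input channels for a sensor subset (``all`` -> 27 channels)."""
    if segment == "all":
        return all_channel_names()
    if segment not in _SEGMENT_SETS:
        raise ValueError(f"unknown segment {segment!r}; "
                         f"choose from {_SEGMENT_SETS}")
    names = [c for c in inertial_channel_names() if c.startswith(segment + "_")]
    if segment != "pelvis":
        names.append(f"angle_{segment}")
    return names


@dataclass
class ModelSpec:
    """Architecture + input-channel configuration."""

    input_channels: list[str] = field(default_factory=all_channel_names)
    lstm_units: int = 64
    lstm_layers: int = 2
    dense: tuple[int, int] = (128, 64)
    dropout: float = 0.2


@dataclass
class TrainConfig:
    """Optimization configuration for one training mode."""

    mode: str = "generalized"          # generalized | fine_tune | individual
    epochs: int = 40
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 0.01
    loss_beta: float = 1.0
    val_fraction: float = 0.1          # generalized 9:1 split
    subseq_hop: int = 1                # training sub-sequence stride
    checkpoint: str = "best"           # best | final
    seed: int = 0

    @classmethod
    def generalized(cls, **kw) -> "TrainConfig":
        return cls(mode="generalized", epochs=kw.pop("epochs", 40),
                   batch_size=kw.pop("batch_size", 32), **kw)

    @classmethod
    def fine_tune(cls, **kw) -> "TrainConfig":
        return cls(mode="fine_tune", epochs=kw.pop("epochs", 15),
                   batch_size=kw.pop("batch_size", 16), **kw)

    @classmethod
    def individual(cls, **kw) -> "TrainConfig":
        return cls(mode="individual", epochs=kw.pop("epochs", 15),
                   batch_size=kw.pop("batch_size", 1), **kw)


@dataclass
class TrainedEstimator:
    """A trained regressor with its normalization and provenance."""

    net: nn.BiLSTMRegressor
    spec: ModelSpec
    norm: NormalizationSpec
    provenance: dict
    history: pd.DataFrame

    def copy(self) -> "TrainedEstimator":
        clone = nn.BiLSTMRegressor.from_config(self.net.config())
        clone.load_state_dict(self.net.state_dict())
        return TrainedEstimator(net=clone, spec=copy.deepcopy(self.spec),
                                norm=copy.deepcopy(self.norm),
                                provenance=copy.deepcopy(self.provenance),
                                history=self.history.copy())


# ---------------------------------------------------------------------------
# Window -> array plumbing
# ---------------------------------------------------------------------------

def window_fingerprint(window: StanceWindow) -> str:
    """Stable content hash of a window's input matrix (leakage checks)."""
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(window.inputs, dtype=np.float64).tobytes())
    return h.hexdigest()


def _channel_indices(window: StanceWindow, channels: Sequence[str]) -> list[int]:
    names = list(window.channel_names)
    missing = [c for c in channels if c not in names]
    if missing:
        raise ValueError(f"windows lack channels {missing}")
    return [names.index(c) for c in channels]


def fit_window_normalization(windows: Sequence[StanceWindow],
                             channels: Sequence[str]) -> NormalizationSpec:
    """Grouped min-max ranges over the training windows' input matrices."""
    if not windows:
        raise ValueError("empty training set")
    idx = _channel_indices(windows[0], channels)
    stacked = np.vstack([np.asarray(w.inputs)[:, idx] for w in windows])
    frame = pd.DataFrame(stacked, columns=list(channels))
    from .signal_prep import fit_normalization
    return fit_normalization(frame, groups=default_groups(channels))


def _norm_bounds(norm: NormalizationSpec, channels: Sequence[str]):
    lo = np.empty(len(channels))
    hi = np.empty(len(channels))
    chan_to_group = {c: g for g, members in norm.groups.items() for c in members}
    for j, c in enumerate(channels):
        lo[j], hi[j] = norm.ranges[chan_to_group[c]]
    return lo, hi


def windows_to_arrays(windows: Sequence[StanceWindow],
                      channels: Sequence[str],
                      norm: NormalizationSpec,
                      hop: int = 1,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (M, 22, C) sub-sequence inputs and (M,) mid-point targets.

    At ``hop > 1`` the slices of each window are subsampled; when an ``rng``
    is supplied each window gets a random phase offset in ``[0, hop)`` so
    the pooled training set covers every stance-phase alignment (all
    windows start at IC - 29, so a fixed grid would always sample the same
    alignments while inference runs at hop 1).
    """
    lo, hi = _norm_bounds(norm, channels)
    xs, ys = [], []
    for w in windows:
        idx = _channel_indices(w, channels)
        mat = (np.asarray(w.inputs)[:, idx] - lo) / (hi - lo)
        if mat.shape[0] < SUBSEQ_LEN:
            continue
        off = int(rng.integers(hop)) if (rng is not None and hop > 1) else 0
        view = np.lib.stride_tricks.sliding_window_view(mat, SUBSEQ_LEN, axis=0)
        view = view.transpose(0, 2, 1)[off::hop]       # (n, 22, C)
        xs.append(view)
        tgt = np.asarray(w.target)[MIDPOINT:mat.shape[0] - (SUBSEQ_LEN - MIDPOINT - 1)]
        ys.append(tgt[off::hop])
    if not xs:
        raise ValueError("no usable windows (all shorter than 22 frames?)")
    X = np.ascontiguousarray(np.concatenate(xs), dtype=nn.DTYPE)
    y = np.concatenate(ys).astype(nn.DTYPE)
    return X, y


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _fit(net: nn.BiLSTMRegressor, X, y, Xval, yval,
         cfg: TrainConfig) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.AdamW(net.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    use_best = cfg.checkpoint == "best" and len(Xval) > 0
    best_val = np.inf
    best_state = net.state_dict() if use_best else None
    rows = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X))
        total = 0.0
        for s in range(0, len(X), cfg.batch_size):
            idx = perm[s:s + cfg.batch_size]
            pred, cache = net.forward(X[idx], train=True, rng=rng)
            total += nn.smooth_l1(pred, y[idx], cfg.loss_beta) * len(idx)
            dy = nn.smooth_l1_grad(pred, y[idx], cfg.loss_beta)
            opt.step(net.backward(dy, cache))
        val = nn.smooth_l1(net.predict(Xval), yval, cfg.loss_beta) \
            if len(Xval) else np.nan
        rows.append({"epoch": epoch, "train_loss": total / len(X),
                     "val_loss": val})
        if use_best and val < best_val:
            best_val = val
            best_state = net.state_dict()
    if use_best and best_state is not None:
        net.load_state_dict(best_state)
    return pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])


def _provenance(cfg: TrainConfig, windows: Sequence[StanceWindow],
                **extra) -> dict:
    prov = {"mode": cfg.mode, "config": asdict(cfg),
            "n_windows": len(windows),
            "fingerprints": sorted(window_fingerprint(w) for w in windows)}
    prov.update(extra)
    return prov


def train_generalized(windows_by_runner: Mapping[str, Sequence[StanceWindow]],
                      cfg: Optional[TrainConfig] = None,
                      spec: Optional[ModelSpec] = None) -> TrainedEstimator:
    """Train a generalized estimator on pooled windows of >= 2 runners.

    Normalization is fit on the pooled training windows; the stance pool is
    split 9:1 (random, seeded) into training and validation at the window
    level.  Returns the estimator with its per-epoch loss log.
    """
    cfg = cfg or TrainConfig.generalized()
    spec = spec or ModelSpec()
    runners = list(windows_by_runner)
    if len(runners) < 2:
        raise ValueError("generalized training needs windows from >= 2 runners")
    windows = [w for r in runners for w in windows_by_runner[r]]
    if not windows:
        raise ValueError("empty training set")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(windows))
    n_val = max(1, int(round(cfg.val_fraction * len(windows))))
    val_idx = set(order[:n_val].tolist())
    train_w = [w for i, w in enumerate(windows) if i not in val_idx]
    val_w = [w for i, w in enumerate(windows) if i in val_idx]

    norm = fit_window_normalization(train_w, spec.input_channels)
    hop_rng = np.random.default_rng(cfg.seed + 2)
    X, y = windows_to_arrays(train_w, spec.input_channels, norm,
                             cfg.subseq_hop, rng=hop_rng)
    Xv, yv = windows_to_arrays(val_w, spec.input_channels, norm,
                               cfg.subseq_hop, rng=hop_rng)

    net = nn.BiLSTMRegressor(n_channels=len(spec.input_channels),
                             hidden=spec.lstm_units, dense=spec.dense,
                             dropout=spec.dropout, t_mid=MIDPOINT,
                             seed=cfg.seed)
    history = _fit(net, X, y, Xv, yv, cfg)
    prov = _provenance(cfg, train_w, runners=runners,
                       val_fingerprints=sorted(window_fingerprint(w)
                                               for w in val_w))
    return TrainedEstimator(net=net, spec=spec, norm=norm,
                            provenance=prov, history=history)


def fine_tune(estimator: TrainedEstimator,
              train_windows: Sequence[StanceWindow],
              val_windows: Sequence[StanceWindow],
              cfg: Optional[TrainConfig] = None,
              source: str = "OG-FP") -> TrainedEstimator:
    """Continue training *all* weights on one runner's stances.

    The pre-trained estimator's normalization is kept (the inputs must stay
    on the scale the weights were trained with).  Provenance records the
    number of fine-tuning stances ``k`` and the source setting.
    """
    cfg = cfg or TrainConfig.fine_tune()
    if not train_windows:
        raise ValueError("empty fine-tuning set")
    out = estimator.copy()
    channels = out.spec.input_channels
    hop_rng = np.random.default_rng(cfg.seed + 2)
    X, y = windows_to_arrays(train_windows, channels, out.norm,
                             cfg.subseq_hop, rng=hop_rng)
    if val_windows:
        Xv, yv = windows_to_arrays(val_windows, channels, out.norm,
                                   cfg.subseq_hop, rng=hop_rng)
    else:
        Xv = np.empty((0, SUBSEQ_LEN, len(channels)), dtype=nn.DTYPE)
        yv = np.empty(0, dtype=nn.DTYPE)
    history = _fit(out.net, X, y, Xv, yv, cfg)
    out.provenance = _provenance(
        cfg, train_windows, k=len(train_windows), source=source,
        base=estimator.provenance.get("mode", "generalized"),
        val_fingerprints=sorted(window_fingerprint(w) for w in val_windows))
    out.history = history
    return out


def train_individual(train_windows: Sequence[StanceWindow],
                     val_windows: Sequence[StanceWindow],
                     cfg: Optional[TrainConfig] = None,
                     spec: Optional[ModelSpec] = None) -> TrainedEstimator:
    """Train from a fresh initialization on a single runner's few stances."""
    cfg = cfg or TrainConfig.individual()
    spec = spec or ModelSpec()
    if not train_windows:
        raise ValueError("empty training set")
    norm = fit_window_normalization(train_windows, spec.input_channels)
    hop_rng = np.random.default_rng(cfg.seed + 2)
    X, y = windows_to_arrays(train_windows, spec.input_channels, norm,
                             cfg.subseq_hop, rng=hop_rng)
    if val_windows:
        Xv, yv = windows_to_arrays(val_windows, spec.input_channels, norm,
                                   cfg.subseq_hop, rng=hop_rng)
    else:
        Xv = np.empty((0, SUBSEQ_LEN, len(spec.input_channels)), dtype=nn.DTYPE)
        yv = np.empty(0, dtype=nn.DTYPE)
    net = nn.BiLSTMRegressor(n_channels=len(spec.input_channels),
                             hidden=spec.lstm_units, dense=spec.dense,
                             dropout=spec.dropout, t_mid=MIDPOINT,
                             seed=cfg.seed)
    history = _fit(net, X, y, Xv, yv, cfg)
    return TrainedEstimator(net=net, spec=spec, norm=norm,
                            provenance=_provenance(cfg, train_windows),
                            history=history)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_waveform(estimator: TrainedEstimator,
                     session: SensorSession | pd.DataFrame,
                     start: int = 0, end: Optional[int] = None) -> np.ndarray:
    """Predict a continuous AP-GRF waveform (%BW) over ``[start, end)``.

    Applies the stored normalization, slides hop-1 22-frame sub-sequences
    over the series, and stitches mid-point predictions; uncovered edge
    frames are NaN.  The returned waveform is indexed on the full session
    frame grid.  Raises ``ValueError`` for a span shorter than 22 frames.
    """
    channels = estimator.spec.input_channels
    frame = session.channels if isinstance(session, SensorSession) else session
    n_frames = len(frame)
    end = n_frames if end is None else end
    if end - start < SUBSEQ_LEN:
        raise ValueError(f"need >= {SUBSEQ_LEN} frames, got {end - start}")
    lo, hi = _norm_bounds(estimator.norm, channels)
    mat = (frame[list(channels)].to_numpy(dtype=float)[start:end] - lo) / (hi - lo)
    view = np.lib.stride_tricks.sliding_window_view(mat, SUBSEQ_LEN, axis=0)
    X = np.ascontiguousarray(view.transpose(0, 2, 1), dtype=nn.DTYPE)
    preds = estimator.net.predict(X)
    t_mid = np.arange(len(preds)) + MIDPOINT + start
    return stitch_predictions(preds.astype(float), t_mid, n_frames)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_estimator(estimator: TrainedEstimator, directory: str | Path) -> Path:
    """Write weights (npz) + a JSON sidecar (spec, normalization, provenance)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **estimator.net.state_dict())
    meta = {
        "net": estimator.net.config(),
        "spec": {"input_channels": list(estimator.spec.input_channels),
                 "lstm_units": estimator.spec.lstm_units,
                 "lstm_layers": estimator.spec.lstm_layers,
                 "dense": list(estimator.spec.dense),
                 "dropout": estimator.spec.dropout},
        "norm": {"groups": {k: list(v) for k, v in estimator.norm.groups.items()},
                 "ranges": {k: [float(a), float(b)]
                            for k, (a, b) in estimator.norm.ranges.items()}},
        "provenance": estimator.provenance,
    }
    (directory / "estimator.json").write_text(json.dumps(meta, indent=2))
    estimator.history.to_csv(directory / "history.csv", index=False)
    return directory


def load_estimator(directory: str | Path) -> TrainedEstimator:
    directory = Path(directory)
    meta = json.loads((directory / "estimator.json").read_text())
    net = nn.BiLSTMRegressor.from_config(meta["net"])
    with np.load(directory / "weights.npz") as state:
        net.load_state_dict({k: state[k] for k in state.files})
    spec = ModelSpec(input_channels=meta["spec"]["input_channels"],
                     lstm_units=meta["spec"]["lstm_units"],
                     lstm_layers=meta["spec"]["lstm_layers"],
                     dense=tuple(meta["spec"]["dense"]),
                     dropout=meta["spec"]["dropout"])
    norm = NormalizationSpec(groups=meta["norm"]["groups"],
                             ranges={k: (v[0], v[1])
                                     for k, v in meta["norm"]["ranges"].items()})
    history = pd.read_csv(directory / "history.csv") \
        if (directory / "history.csv").exists() else pd.DataFrame()
    return TrainedEstimator(net=net, spec=spec, norm=norm,
                            provenance=meta["provenance"], history=history)
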