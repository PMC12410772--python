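"""Experiment drivers: leave-one-runner-out CV, stride sweep, sensor ablation.

Configurations mirror the study design:

========  =====================  ===========================  ================
name      trained on             fine-tuned on                tested on
========  =====================  ===========================  ================
GEN-TM    treadmill, N-1 runners --                           held-out runner,
FTN-TM    treadmill, N-1 runners held-out runner's treadmill  overground
FTN-OG    treadmill, N-1 runners held-out runner's overground split B stances
IND-OG    held-out runner's overground split A (from scratch)
========  =====================  ===========================  ================

A runner's overground stances are split chronologically: the first half
(split A) is the fine-tuning pool, the second half (split B) the test set;
fine-tuning uses the chronologically first ``k`` stances of the pool and a
fixed four-stance validation set (the last four of the pool), so the
validation stances do not change with ``k``.  Errors are stance-restricted
RMSE in %BW, pooled over the test stances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .impulse import (
    attach_speeds,
    compare_fits,
    compute_impulses,
    speed_impulse_fit,
)
from .model import (
    ModelSpec,
    TrainConfig,
    TrainedEstimator,
    fine_tune,
    predict_waveform,
    select_channels,
    train_generalized,
    train_individual,
    window_fingerprint,
)
from .segmentation import (
    GaitEvents,
    StanceWindow,
    SwingRule,
    detect_gait_events_from_prediction,
    detect_stance_from_force,
    extend_window,
    fill_window,
)
from .session import SensorSession
from .signal_prep import condition_session, force_to_percent_bw
from .synthetic import SyntheticDataset

log = logging.getLogger(__name__)

CONFIGURATIONS = ("GEN-TM", "FTN-TM", "FTN-OG", "IND-OG")
STRIDE_COUNTS = (2, 4, 8, 14, 20)
SENSOR_SETS = ("all", "foot", "shank", "thigh", "pelvis")


@dataclass
class ExperimentPlan:
    """What to run and at what (scaled) training sizes."""

    configurations: tuple = CONFIGURATIONS
    stride_counts: tuple = (8,)
    sensor_sets: tuple = ("all",)
    seeds: tuple = (0,)
    n_finetune_val: int = 4
    gen_epochs: int = 40
    ft_epochs: int = 15
    ind_epochs: int = 15
    gen_hop: int = 1       # training sub-sequence stride (inference stays hop 1)
    ft_hop: int = 1
    max_test_stances: Optional[int] = None   # cap split-B stances scored
    include_zero: bool = True                # score the zero-predictor baseline
    ind_stride_counts: Optional[tuple] = None  # IND-OG k values (default: all)
    ft_selection: str = "first"              # fine-tune stances: first | random

    def __post_init__(self) -> None:
        unknown = set(self.configurations) - set(CONFIGURATIONS)
        if unknown:
            raise ValueError(f"unknown configurations {unknown}")
        unknown = set(self.sensor_sets) - set(SENSOR_SETS)
        if unknown:
            raise ValueError(f"unknown sensor sets {unknown}")
        if not self.sensor_sets:
            raise ValueError("empty sensor set list")
        if self.ft_selection not in ("first", "random"):
            raise ValueError("ft_selection must be 'first' or 'random'")


@dataclass
class PreparedSession:
    """A conditioned session with its force-derived targets and windows.

    ``window_event_idx[i]`` is the force-event (stance) index of
    ``windows[i]``; clipped boundary stances have windows dropped, so the
    two lists are not positionally aligned with ``events``.
    """

    session: SensorSession
    ap_bw: Optional[np.ndarray]          # measured AP-GRF, %BW, IMU grid
    events: Optional[GaitEvents]         # force-threshold stances
    windows: list                        # unclipped, filled StanceWindows
    window_event_idx: list = field(default_factory=list)


def prepare_session(raw: SensorSession) -> PreparedSession:
    """Condition a session and, when force is present, build stance windows."""
    sess = condition_session(raw)
    ap_bw = events = None
    windows: list[StanceWindow] = []
    event_idx: list[int] = []
    if sess.has_force:
        ap_bw = force_to_percent_bw(sess.force_ap, sess.bodyweight)
        events = detect_stance_from_force(sess.force_vertical)
        chans = list(sess.channels.columns)
        mat = sess.channels.to_numpy(dtype=float)
        for i, w in enumerate(extend_window(events, sess.n_frames)):
            if w.clipped:
                continue
            windows.append(fill_window(w, mat, ap_bw, chans))
            event_idx.append(i)
    return PreparedSession(session=sess, ap_bw=ap_bw, events=events,
                           windows=windows, window_event_idx=event_idx)


def prepare_dataset(dataset: SyntheticDataset) -> dict:
    """Prepare every session of a dataset once; keyed (runner_id, setting)."""
    return {key: prepare_session(sess)
            for key, sess in dataset.sessions.items()}


def stance_rmse(predicted: np.ndarray, reference: np.ndarray,
                events: GaitEvents,
                stance_subset: Optional[Sequence[int]] = None) -> float:
    """RMSE (%BW) over stance frames only, pooled across stances.

    Swing frames never enter the error; NaN (uncovered) frames are skipped.
    ``stance_subset`` restricts pooling to the given stance indices.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = range(events.n_stances) if stance_subset is None else stance_subset
    errs = []
    for k in idx:
        ic, to = events.ic_frames[k], events.to_frames[k]
        p = predicted[ic:to]
        r = reference[ic:to]
        ok = ~np.isnan(p) & ~np.isnan(r)
        errs.append((p[ok] - r[ok]) ** 2)
    pooled = np.concatenate(errs) if errs else np.empty(0)
    if pooled.size == 0:
        raise ValueError("no stance frames to score")
    return float(np.sqrt(np.mean(pooled)))


def _split_ab(windows: Sequence[StanceWindow]) -> tuple[list, list]:
    """Chronological first half = fine-tune pool A, second half = test B."""
    half = len(windows) // 2
    return list(windows[:half]), list(windows[half:])


def _check_disjoint(train_prov: dict, test_windows: Sequence[StanceWindow]):
    train_fp = set(train_prov.get("fingerprints", [])) \
        | set(train_prov.get("val_fingerprints", []))
    test_fp = {window_fingerprint(w) for w in test_windows}
    overlap = train_fp & test_fp
    if overlap:
        raise RuntimeError(f"data leakage: {len(overlap)} test stances "
                           f"appear in a training set")


@dataclass
class FoldModels:
    """All estimators trained for one (held-out runner, seed, sensor set)."""

    runner_id: str
    seed: int
    sensor_set: str
    gen: TrainedEstimator
    ftn_og: dict            # k -> estimator
    ftn_tm: dict
    ind_og: dict
    split_a: list
    split_b: list


def train_fold(prepared: dict, dataset: SyntheticDataset, runner_id: str,
               seed: int, plan: ExperimentPlan,
               sensor_set: str = "all") -> FoldModels:
    """Train every requested configuration for one held-out runner."""
    spec = ModelSpec(input_channels=select_channels(sensor_set))
    train_runners = [r for r in dataset.runner_ids if r != runner_id]
    by_runner = {r: prepared[(r, "TM-FP")].windows for r in train_runners}
    gen = train_generalized(
        by_runner,
        TrainConfig.generalized(seed=seed, epochs=plan.gen_epochs,
                                subseq_hop=plan.gen_hop),
        spec)

    og = prepared[(runner_id, "OG-FP")]
    tm = prepared[(runner_id, "TM-FP")]
    split_a, split_b = _split_ab(og.windows)
    tm_a, _ = _split_ab(tm.windows)

    n_val = plan.n_finetune_val
    if len(split_a) < max(plan.stride_counts) + n_val:
        raise ValueError(
            f"fine-tune pool of {runner_id} has {len(split_a)} stances; "
            f"needs >= {max(plan.stride_counts) + n_val}")
    val_og = split_a[-n_val:]
    val_tm = tm_a[-n_val:]
    pool_og = split_a[:-n_val]
    pool_tm = tm_a[:-n_val]
    if plan.ft_selection == "random":
        sel_rng = np.random.default_rng(seed + 10)
        pool_og = [pool_og[i] for i in sel_rng.permutation(len(pool_og))]
        pool_tm = [pool_tm[i] for i in sel_rng.permutation(len(pool_tm))]

    ind_ks = plan.ind_stride_counts if plan.ind_stride_counts is not None \
        else plan.stride_counts
    ftn_og, ftn_tm, ind_og = {}, {}, {}
    for k in plan.stride_counts:
        train_k = pool_og[:k]
        if "FTN-OG" in plan.configurations:
            ftn_og[k] = fine_tune(
                gen, train_k, val_og,
                TrainConfig.fine_tune(seed=seed, epochs=plan.ft_epochs,
                                      subseq_hop=plan.ft_hop),
                source="OG-FP")
        if "IND-OG" in plan.configurations and k in ind_ks:
            ind_og[k] = train_individual(
                train_k, val_og,
                TrainConfig.individual(seed=seed, epochs=plan.ind_epochs,
                                       subseq_hop=plan.ft_hop),
                spec)
        if "FTN-TM" in plan.configurations:
            ftn_tm[k] = fine_tune(
                gen, pool_tm[:k], val_tm,
                TrainConfig.fine_tune(seed=seed, epochs=plan.ft_epochs,
                                      subseq_hop=plan.ft_hop),
                source="TM-FP")

    for est in [gen] + list(ftn_og.values()) + list(ftn_tm.values()) \
            + list(ind_og.values()):
        _check_disjoint(est.provenance, split_b)

    return FoldModels(runner_id=runner_id, seed=seed, sensor_set=sensor_set,
                      gen=gen, ftn_og=ftn_og, ftn_tm=ftn_tm, ind_og=ind_og,
                      split_a=split_a, split_b=split_b)


def evaluate_fold(fold: FoldModels, prepared: dict,
                  plan: ExperimentPlan) -> pd.DataFrame:
    """Stance-restricted test RMSE of every estimator in a fold."""
    og = prepared[(fold.runner_id, "OG-FP")]
    sess = og.session
    n_a = len(og.windows) // 2
    b_positions = list(range(n_a, len(og.windows)))
    if plan.max_test_stances is not None:
        b_positions = b_positions[:plan.max_test_stances]
    b_stances = [og.window_event_idx[i] for i in b_positions]
    start = max(og.windows[b_positions[0]].window_start - 11, 0) \
        if b_positions else 0
    end = min(og.windows[b_positions[-1]].window_end + 11, sess.n_frames) \
        if b_positions else sess.n_frames

    zero = np.zeros(sess.n_frames)
    rows = []

    def score(name: str, k, est: Optional[TrainedEstimator]):
        if est is None:
            rmse = stance_rmse(zero, og.ap_bw, og.events, b_stances)
        else:
            wave = predict_waveform(est, sess, start=start, end=end)
            rmse = stance_rmse(wave, og.ap_bw, og.events, b_stances)
        rows.append({"runner_id": fold.runner_id, "seed": fold.seed,
                     "sensor_set": fold.sensor_set, "configuration": name,
                     "stride_count": k, "stance_rmse_bw": rmse,
                     "n_test_stances": len(b_stances)})

    if plan.include_zero:
        score("ZERO", np.nan, None)
    if "GEN-TM" in plan.configurations:
        score("GEN-TM", np.nan, fold.gen)
    for k in plan.stride_counts:
        if k in fold.ftn_og:
            score("FTN-OG", k, fold.ftn_og[k])
        if k in fold.ftn_tm:
            score("FTN-TM", k, fold.ftn_tm[k])
        if k in fold.ind_og:
            score("IND-OG", k, fold.ind_og[k])
    return pd.DataFrame(rows)


def run_loocv(dataset: SyntheticDataset, plan: ExperimentPlan,
              prepared: Optional[dict] = None,
              return_models: bool = False):
    """Leave-one-runner-out evaluation over every (runner, seed).

    Returns a tidy result table (one row per runner/seed/configuration/k),
    and optionally the trained fold models for reuse by validation drivers.
    """
    prepared = prepared if prepared is not None else prepare_dataset(dataset)
    tables, models = [], []
    for seed in plan.seeds:
        for runner_id, _ in dataset.loocv_partitions():
            for sensor_set in plan.sensor_sets:
                fold = train_fold(prepared, dataset, runner_id, seed, plan,
                                  sensor_set)
                tables.append(evaluate_fold(fold, prepared, plan))
                if return_models:
                    models.append(fold)
                log.info("fold done: runner=%s seed=%d sensors=%s",
                         runner_id, seed, sensor_set)
    table = pd.concat(tables, ignore_index=True)
    return (table, models) if return_models else table


def stride_sweep(dataset: SyntheticDataset, plan: ExperimentPlan,
                 prepared: Optional[dict] = None) -> pd.DataFrame:
    """Fine-tuning stride-count sweep (FTN-OG/FTN-TM rows over all k)."""
    sweep_plan = replace(
        plan,
        configurations=tuple(c for c in plan.configurations
                             if c in ("GEN-TM", "FTN-OG", "FTN-TM")),
        stride_counts=plan.stride_counts or STRIDE_COUNTS)
    return run_loocv(dataset, sweep_plan, prepared)


def sensor_ablation(dataset: SyntheticDataset, plan: ExperimentPlan,
                    prepared: Optional[dict] = None) -> pd.DataFrame:
    """Retrain per sensor subset; per-runner grid of stance RMSE."""
    ablation_plan = replace(
        plan,
        configurations=tuple(c for c in plan.configurations
                             if c in ("GEN-TM", "FTN-OG")),
        sensor_sets=plan.sensor_sets or SENSOR_SETS)
    return run_loocv(dataset, ablation_plan, prepared)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD of stance RMSE across runners (and seeds) per cell."""
    grouped = table.groupby(["configuration", "stride_count", "sensor_set"],
                            dropna=False)["stance_rmse_bw"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "rmse_mean", "std": "rmse_sd",
                               "count": "n"})


# ---------------------------------------------------------------------------
# Speed-impulse validation on sessions without force truth
# ---------------------------------------------------------------------------

def reference_impulse_points(prep: PreparedSession):
    """Force-plate impulse points (with speeds) from an OG-FP session."""
    pts = compute_impulses(prep.ap_bw, prep.events,
                           prep.session.frame_rate, source="force_plate")
    return attach_speeds(pts, prep.events, prep.session.speed_trace)


def predicted_impulse_points(est, prep: PreparedSession,
                             rule: SwingRule = SwingRule()):
    """Impulse points from model predictions on a force-free session.

    ``est`` is a :class:`TrainedEstimator`, or any callable mapping a
    session to a waveform (e.g. an oracle in tests).
    """
    sess = prep.session
    wave = est(sess) if callable(est) else predict_waveform(est, sess)
    events = detect_gait_events_from_prediction(wave, rule, sess.frame_rate)
    if events.n_stances == 0:
        raise ValueError("prediction-based segmentation found no stances")
    pts = compute_impulses(wave, events, sess.frame_rate, source="prediction")
    return attach_speeds(pts, events, sess.speed_trace)


def validate_setting(estimators: dict, target_preps: Sequence[PreparedSession],
                     reference_points, rule: SwingRule = SwingRule()
                     ) -> pd.DataFrame:
    """Speed-impulse plausibility check where no force plates exist.

    For each named estimator: predict AP-GRF on the force-free sessions,
    segment stances from the predictions, integrate braking/propulsion
    impulses with per-stance speeds, fit the weighted speed-impulse line,
    and report its RMSE against the force-plate reference line on the
    25-point grid plus the fit's R^2 — one row per (estimator, metric).
    """
    rows = []
    ref_fits = {m: speed_impulse_fit(reference_points, m)
                for m in ("braking_impulse", "propulsion_impulse")}
    for name, est in estimators.items():
        points = []
        for prep in target_preps:
            points.extend(predicted_impulse_points(est, prep, rule))
        for metric, ref in ref_fits.items():
            fit = speed_impulse_fit(points, metric)
            cmp_ = compare_fits(ref, fit)
            rows.append({"estimator": name,
                         "metric": metric.replace("_impulse", ""),
                         "fit_rmse_bw_s": cmp_.rmse,
                         "r_squared": fit.r_squared,
                         "slope": fit.slope,
                         "ref_slope": ref.slope,
                         "n_stances": len(points)})
    return pd.DataFrame(rows)
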