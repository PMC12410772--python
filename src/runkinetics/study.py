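"""A desk-scale reference study over the full pipeline.

Runs the complete experiment matrix on a synthetic cohort sized for a
single CPU: six runners with treadmill + overground sessions (three of them
with an outdoor session), ~140 stances per session, leave-one-runner-out
cross validation over three seeds, a fine-tuning stride sweep (k = 2, 8,
20), prediction-based gait-event scoring, and the speed-impulse validation
of outdoor predictions against the overground force-plate reference.

Both the test suite and ``scripts/acceptance.py`` drive this entry point so
the numbers they report come from one place.  Problem sizes and reduced
epoch counts are this module's scaling choices and are documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .experiments import (
    ExperimentPlan,
    FoldModels,
    evaluate_fold,
    prepare_dataset,
    reference_impulse_points,
    summarize,
    train_fold,
    validate_setting,
)
from .model import predict_waveform
from .segmentation import (
    SwingRule,
    detect_gait_events_from_prediction,
    event_rmse,
)
from .synthetic import SimConfig, make_dataset


@dataclass
class StudyConfig:
    """Cohort and training sizes for the desk-scale study."""

    seed: int = 0
    n_runners: int = 6
    n_outdoor: int = 3
    duration_s: float = 105.0        # ~140 unilateral stances per session
    n_seeds: int = 3
    stride_counts: tuple = (2, 8, 20)
    ind_stride_counts: tuple = (8,)  # individual-only models trained at k=8
    gen_epochs: int = 4
    ft_epochs: int = 5
    ind_epochs: int = 3
    gen_hop: int = 12                # training sub-sequence stride, GEN
    ft_hop: int = 2
    max_test_stances: int = 45       # split-B stances scored per runner


@dataclass
class StudyResult:
    """All tables the study produces."""

    loocv: pd.DataFrame              # per runner/seed/configuration/k RMSE
    summary: pd.DataFrame            # mean +- SD per configuration/k
    validation: pd.DataFrame         # speed-impulse fit comparisons (OUT)
    events: pd.DataFrame             # prediction-derived gait-event timing
    manifest: pd.DataFrame


def _plan(cfg: StudyConfig) -> ExperimentPlan:
    return ExperimentPlan(
        configurations=("GEN-TM", "FTN-OG", "IND-OG"),
        stride_counts=cfg.stride_counts,
        seeds=tuple(cfg.seed + i for i in range(cfg.n_seeds)),
        gen_epochs=cfg.gen_epochs, ft_epochs=cfg.ft_epochs,
        ind_epochs=cfg.ind_epochs, gen_hop=cfg.gen_hop, ft_hop=cfg.ft_hop,
        max_test_stances=cfg.max_test_stances,
        ind_stride_counts=cfg.ind_stride_counts)


def run_study(cfg: StudyConfig = StudyConfig(),
              progress: bool = False) -> StudyResult:
    """Run LOOCV + stride sweep + event scoring + outdoor validation."""
    ds = make_dataset(SimConfig(seed=cfg.seed + 101,
                                duration=cfg.duration_s,
                                n_runners=cfg.n_runners,
                                n_outdoor=cfg.n_outdoor))
    prepared = prepare_dataset(ds)
    plan = _plan(cfg)

    loocv_rows, val_rows, event_rows = [], [], []
    outdoor_ids = set(ds.manifest.loc[ds.manifest.setting == "OUT",
                                      "runner_id"])
    for seed in plan.seeds:
        for runner_id, _ in ds.loocv_partitions():
            fold = train_fold(prepared, ds, runner_id, seed, plan)
            table = evaluate_fold(fold, prepared, plan)
            loocv_rows.append(table)
            event_rows.append(_score_events(fold, prepared, seed))
            if runner_id in outdoor_ids:
                val_rows.append(_validate_outdoor(fold, prepared, seed))
            if progress:
                print(f"fold runner={runner_id} seed={seed} done", flush=True)

    loocv = pd.concat(loocv_rows, ignore_index=True)
    validation = pd.concat(val_rows, ignore_index=True)
    events = pd.DataFrame(event_rows)
    return StudyResult(loocv=loocv, summary=summarize(loocv),
                       validation=validation, events=events,
                       manifest=ds.manifest)


def _score_events(fold: FoldModels, prepared: dict, seed: int) -> dict:
    """Gait-event timing of prediction-derived IC/TO on the OG test region."""
    og = prepared[(fold.runner_id, "OG-FP")]
    est = fold.ftn_og[max(fold.ftn_og)]
    half = og.windows[len(og.windows) // 2].window_start
    wave = predict_waveform(est, og.session, start=max(half - 11, 0))
    pred_events = detect_gait_events_from_prediction(
        wave, SwingRule(), og.session.frame_rate)
    scores = event_rmse(pred_events, og.events, og.session.frame_rate)
    scores.update({"runner_id": fold.runner_id, "seed": seed})
    return scores


def _validate_outdoor(fold: FoldModels, prepared: dict, seed: int
                      ) -> pd.DataFrame:
    """Speed-impulse validation of GEN vs fine-tuned estimators outdoors."""
    ref_points = reference_impulse_points(prepared[(fold.runner_id, "OG-FP")])
    out_prep = prepared[(fold.runner_id, "OUT")]
    k_mid = 8 if 8 in fold.ftn_og else max(fold.ftn_og)
    table = validate_setting({"GEN-TM": fold.gen, "FTN-OG": fold.ftn_og[k_mid]},
                             [out_prep], ref_points)
    table["runner_id"] = fold.runner_id
    table["seed"] = seed
    return table


# ---------------------------------------------------------------------------
# Headline numbers
# ---------------------------------------------------------------------------

def headline_numbers(res: StudyResult) -> dict:
    """Aggregate the study into the pipeline's headline quantities."""
    s = res.summary

    def mean_rmse(config: str, k=None) -> float:
        rows = s[s.configuration == config]
        if k is not None:
            rows = rows[rows.stride_count == k]
        return float(rows.rmse_mean.mean())

    per_runner = res.loocv
    gen = per_runner[per_runner.configuration == "GEN-TM"]
    zero = per_runner[per_runner.configuration == "ZERO"]
    merged = gen.merge(zero, on=["runner_id", "seed"], suffixes=("_gen", "_zero"))
    frac_beats_zero = float(
        (merged.stance_rmse_bw_gen < merged.stance_rmse_bw_zero).mean())

    val = res.validation
    val_mean = val.groupby(["estimator", "metric"])["fit_rmse_bw_s"].mean()

    ev = res.events
    return {
        "gen_tm_rmse_bw": mean_rmse("GEN-TM"),
        "ftn_og_rmse_bw_k8": mean_rmse("FTN-OG", 8),
        "ftn_og_rmse_bw_k2": mean_rmse("FTN-OG", 2),
        "ftn_og_rmse_bw_k20": mean_rmse("FTN-OG", 20),
        "ind_og_rmse_bw_k8": mean_rmse("IND-OG", 8),
        "zero_predictor_rmse_bw": mean_rmse("ZERO"),
        "gen_beats_zero_fraction": frac_beats_zero,
        "ic_rmse_s": float(ev.ic_rmse_s.mean()),
        "to_rmse_s": float(ev.to_rmse_s.mean()),
        "out_fit_rmse_braking_gen": float(val_mean.get(("GEN-TM", "braking"), np.nan)),
        "out_fit_rmse_braking_ftn": float(val_mean.get(("FTN-OG", "braking"), np.nan)),
        "out_fit_rmse_propulsion_gen": float(val_mean.get(("GEN-TM", "propulsion"), np.nan)),
        "out_fit_rmse_propulsion_ftn": float(val_mean.get(("FTN-OG", "propulsion"), np.nan)),
    }
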