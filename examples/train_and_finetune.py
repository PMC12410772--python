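"""Train a generalized estimator, fine-tune it, and compare test errors.

Small-scale version of the transfer experiment: a generalized model is
trained on two runners' treadmill sessions and evaluated on a third,
held-out runner's overground stances; fine-tuning on eight of that
runner's own overground stances then individualizes it.  Expect a few
minutes of CPU time.
"""

from runkinetics import SimConfig, make_dataset
from runkinetics.experiments import (
    ExperimentPlan,
    evaluate_fold,
    prepare_dataset,
    train_fold,
)

ds = make_dataset(SimConfig(seed=5, duration=45.0, n_runners=3, n_outdoor=0))
prepared = prepare_dataset(ds)

plan = ExperimentPlan(configurations=("GEN-TM", "FTN-OG", "IND-OG"),
                      stride_counts=(8,), seeds=(0,),
                      gen_epochs=3, ft_epochs=5, ind_epochs=3,
                      gen_hop=6, ft_hop=2)
held_out = ds.runner_ids[-1]
print(f"training on {[r for r in ds.runner_ids if r != held_out]}, "
      f"testing on {held_out} ...")
fold = train_fold(prepared, ds, held_out, seed=0, plan=plan)
table = evaluate_fold(fold, prepared, plan)
print(table[["configuration", "stride_count",
             "stance_rmse_bw"]].to_string(index=False))

print("""
stance_rmse_bw is the RMSE (in percent bodyweight) between predicted and
force-plate AP-GRF over stance frames of the held-out runner's overground
test stances.  ZERO is the always-zero baseline (the RMS of the true force);
GEN-TM transfers from other runners' treadmill data; FTN-OG fine-tunes it
with 8 of the test runner's own overground stances and is typically the
most accurate; IND-OG trains on those same 8 stances from scratch and
typically cannot compete.""")
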