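"""Validate force estimates without force plates via impulse-speed fits.

Braking and propulsion impulses grow linearly with running speed.  Where no
force plates exist, predictions can therefore be validated by comparing the
weighted linear fit of predicted impulse vs speed to the fit obtained from
force-plate data: stances are binned into 25 speed bins of 0.1 m/s over
[2.0, 4.5), sparse bins (< 3 stances) are dropped, observations are
weighted by 1/variance of their bin, and the two lines are compared by
RMSE over the 25 bin centers.

Here an "oracle" predictor (the hidden truth of an outdoor session) is
compared to the same runner's overground force-plate fit.
"""

from runkinetics import SimConfig, make_dataset
from runkinetics.experiments import (
    prepare_dataset,
    predicted_impulse_points,
    reference_impulse_points,
)
from runkinetics.impulse import compare_fits, speed_impulse_fit

ds = make_dataset(SimConfig(seed=9, duration=60.0, n_runners=1, n_outdoor=1,
                            speed_segment_s=8.0))
prepared = prepare_dataset(ds)
rid = ds.runner_ids[0]

ref_points = reference_impulse_points(prepared[(rid, "OG-FP")])
truth_out = ds.truth(rid, "OUT")
points = predicted_impulse_points(lambda s: truth_out.ap_grf_bw,
                                  prepared[(rid, "OUT")])

for metric in ("braking_impulse", "propulsion_impulse"):
    ref = speed_impulse_fit(ref_points, metric)
    fit = speed_impulse_fit(points, metric)
    cmp_ = compare_fits(ref, fit)
    name = metric.replace("_impulse", "")
    print(f"{name:10s}: reference slope {ref.slope:+.3f} %BW.s/(m/s) "
          f"(R2 {ref.r_squared:.2f}), candidate slope {fit.slope:+.3f} "
          f"(R2 {fit.r_squared:.2f}), line RMSE {cmp_.rmse:.3f} %BW.s")

print("""
A small line RMSE means the candidate's impulse-speed relationship matches
the force-plate reference; an oracle predictor should agree closely, while
a model that misestimates propulsion produces a visibly offset line.""")
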