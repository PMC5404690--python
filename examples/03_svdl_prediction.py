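"""Statistical voxel dose learning: V_<15Gy, full DVH and 3D dose.

Training liver voxels are pooled into distance-to-target bins; each bin's
dose histogram is summarized (here by its median) and applied per voxel to
a new patient.  The scalar summary supports a full 3D dose prediction; the
fitting summaries (skew-normal, non-parametric) support V_<15Gy and DVH
but refuse 3D dose.
"""

import numpy as np

from liverkbp import (
    CapabilityError,
    actual_dvh,
    actual_v15,
    build_distance_dose_table,
    case_distances,
    estimate_bins,
    generate_cohort,
    predict_dose_3d,
    predict_dvh,
    predict_v15_svdl,
    rss_dvh,
)

cases, _ = generate_cohort(n=10, mode="isotropic", seed=7)
train, test = cases[:-1], cases[-1]

table = build_distance_dose_table(train, bin_width=2.5)
print(f"pooled {table.n_samples} training voxels from {table.n_patients} "
      f"patients into {len(table.bins)} distance bins of 2.5 mm")

est = estimate_bins(table, "median")
d = case_distances(test)

v15_pred = predict_v15_svdl(est, d)
v15_true = actual_v15(test).v15_normalized
print(f"V<15Gy: predicted {v15_pred:.1f}%, actual {v15_true:.1f}%")

dvh_true = actual_dvh(test)
dvh_pred = predict_dvh(est, d, dose_axis=dvh_true.dose_axis)
print(f"RSS_DVH = {rss_dvh(dvh_true, dvh_pred):.5f} "
      f"(sum of squared DVH differences x dose-step^2; lower is better)")

grid = predict_dose_3d(est, test)
err = grid[test.oar_mask] - test.dose[test.oar_mask]
print(f"3D dose: MSE_D = {np.mean(err**2):.2f} Gy^2 over "
      f"{test.oar_mask.sum()} liver voxels")

try:
    predict_dose_3d(estimate_bins(table, "skew_normal"), test)
except CapabilityError as exc:
    print(f"as expected, refused: {exc}")
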