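"""Predict liver V_<15Gy from geometry alone with OVH regression.

The overlap volume histogram's expansion distance r_v (the distance at
which a fraction v of the liver overlaps the expanded target) correlates
linearly with the normalized liver V_<15Gy across a cohort.  The fitted
line predicts a new patient's V_<15Gy before any plan exists.
"""

from liverkbp import (
    actual_v15,
    compute_ovh,
    expansion_distance_at,
    fit_ovh_model,
    generate_cohort,
    predict_v15,
    select_best_v,
)

cases, _ = generate_cohort(n=10, mode="isotropic", seed=7)
train, test = cases[:-1], cases[-1]

curves = {c.case_id: compute_ovh(c) for c in cases}
v15 = [actual_v15(c).v15_normalized for c in train]

# screen candidate overlap fractions for the best correlation
cohort_rv = {v: [expansion_distance_at(curves[c.case_id], v) for c in train]
             for v in (0.05, 0.10, 0.15, 0.20, 0.30)}
best_v, corrs = select_best_v(cohort_rv, v15)
print("candidate v -> Pearson r:",
      {f"{v:.0%}": round(r, 3) for v, r in corrs.items()})
print(f"best candidate: v = {best_v:.0%}")

model = fit_ovh_model(cohort_rv[best_v], v15, v=best_v)
print(f"fit: V<15Gy% = {model.slope:.1f} * r_{best_v:.0%} + "
      f"{model.intercept:.1f}  (r = {model.pearson_r:.3f})")

rv_new = expansion_distance_at(curves[test.case_id], best_v)
predicted = predict_v15(model, rv_new)
actual = actual_v15(test).v15_normalized
print(f"held-out patient: r_v = {rv_new:.2f} cm, predicted V<15Gy "
      f"{predicted:.1f}%, actual {actual:.1f}%")
# the prediction uses only the held-out patient's geometry (masks), never
# its dose — that is the knowledge-based-planning premise.
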