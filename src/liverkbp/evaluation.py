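"""Leave-one-out cross validation and prediction-error metrics.

Each patient is left out of the training cohort in turn; the model (OVH
regression or an SVDL variant) is refit on the remaining patients and used
to predict the held-out patient.  Three metrics quantify agreement, each
applied only where the method's capability matrix allows:

* percent error on V_<15Gy:  |actual - predicted| / actual * 100
* RSS_DVH = sum_D ((DVH_a(D) - DVH_p(D)) * dD)^2  (fitting + scalar SVDL)
* MSE_D = mean over OAR voxels of (D_actual - D_predicted)^2, in Gy^2
  (scalar SVDL only)

A paired one-tailed t-test compares per-patient errors between two plan
styles (the isotropic-like non-coplanar plans are hypothesized to be more
predictable than coplanar ones); results are significant at p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import DVHCurve, PatientCase, actual_dvh
from .errors import DimensionError, LiverKBPError
from .geometry import compute_ovh, expansion_distance_at
from .ovh_model import actual_v15, fit_ovh_model, predict_v15
from .svdl import (
    SCALAR_METHODS,
    DEFAULT_BIN_WIDTH_MM,
    DEFAULT_DOSE_STEP_GY,
    DEFAULT_RESAMPLE_SIZE,
    build_distance_dose_table,
    case_distances,
    estimate_bins,
    predict_dvh,
    predict_v15_svdl,
    predict_voxel_doses,
)

logger = logging.getLogger(__name__)


def percent_error(actual: float, predicted: float) -> float:
    """|actual - predicted| / actual * 100; requires actual > 0."""
    if actual <= 0:
        raise ValueError(f"percent error undefined for actual={actual} <= 0")
    return abs(actual - predicted) / actual * 100.0


def rss_dvh(actual: DVHCurve, predicted: DVHCurve) -> float:
    """Residual sum of squares between two DVHs: sum(((a - p) * dD)^2).

    Low values indicate good agreement across the whole curve.  If the dose
    axes differ, the predicted curve is resampled onto the actual axis by
    linear interpolation (logged).
    """
    a_axis = actual.dose_axis
    if predicted.dose_axis.shape != a_axis.shape or \
            not np.allclose(predicted.dose_axis, a_axis):
        logger.info("rss_dvh: resampling predicted DVH onto the actual dose axis")
        # beyond the predicted curve's range the DVH continues at its end values
        p = np.interp(a_axis, predicted.dose_axis, predicted.volume_fraction)
    else:
        p = predicted.volume_fraction
    dd = actual.dose_step
    return float(np.sum(((actual.volume_fraction - p) * dd) ** 2))


def mse_dose(actual_dose: np.ndarray, predicted_dose: np.ndarray,
             oar_mask: np.ndarray) -> float:
    """Mean squared per-voxel dose difference (Gy^2) over the OAR."""
    oar_mask = np.asarray(oar_mask, dtype=bool)
    if not (actual_dose.shape == predicted_dose.shape == oar_mask.shape):
        raise DimensionError("dose grids and mask must share one shape")
    n = int(oar_mask.sum())
    if n == 0:
        raise ValueError("empty OAR mask")
    diff = actual_dose[oar_mask] - predicted_dose[oar_mask]
    return float(np.mean(diff ** 2))


@dataclass
class TTestResult:
    """Paired one-tailed t-test outcome (alternative: a < b)."""

    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_one_tailed_ttest(errors_a: Sequence[float],
                            errors_b: Sequence[float]) -> TTestResult:
    """Paired one-tailed t-test of H1: mean(a) < mean(b).

    Pairs are matched by patient.  All-zero differences give the t = 0
    convention p = 0.5; constant non-zero differences have zero variance and
    an undefined t — flagged degenerate with p = NaN rather than fabricated.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be matching 1D sequences")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return TTestResult(t=0.0, p=0.5, n=n)
        return TTestResult(t=np.nan, p=np.nan, n=n, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(stats.t.cdf(t, df=n - 1))
    return TTestResult(t=float(t), p=p, n=n)


@dataclass
class OVHPredictorConfig:
    """LOOCV configuration for the OVH regression route."""

    kind: Literal["ovh"] = "ovh"
    v: float = 0.10
    threshold: float = 15.0

    @property
    def label(self) -> str:
        return "ovh"


@dataclass
class SVDLPredictorConfig:
    """LOOCV configuration for an SVDL variant."""

    method: str = "median"
    bin_width: float = DEFAULT_BIN_WIDTH_MM
    threshold: float = 15.0
    dose_step: float = DEFAULT_DOSE_STEP_GY
    resample_size: int = DEFAULT_RESAMPLE_SIZE
    seed: int | None = None
    kind: Literal["svdl"] = "svdl"

    @property
    def label(self) -> str:
        return f"svdl-{self.method}"


@dataclass
class CohortEvaluation:
    """Per-patient LOOCV rows plus summary statistics for one method.

    ``table`` has one row per patient with columns case_id, method,
    actual_v15, predicted_v15, percent_error_v15, rss_dvh, mse_dose; metrics
    a method cannot produce are NaN (not applicable), never silently zero.
    """

    table: pd.DataFrame
    method: str
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        metrics = ["percent_error_v15", "rss_dvh", "mse_dose"]
        rows = {}
        for m in metrics:
            col = self.table[m].dropna()
            if col.empty:
                rows[m] = {"mean": np.nan, "median": np.nan, "q25": np.nan,
                           "q75": np.nan, "n": 0}
            else:
                rows[m] = {"mean": col.mean(), "median": col.median(),
                           "q25": col.quantile(0.25), "q75": col.quantile(0.75),
                           "n": int(col.size)}
        return pd.DataFrame(rows).T

    def boxplot_stats(self, metric: str = "percent_error_v15") -> dict:
        """Median, quartiles, 1.5*IQR whiskers and outliers for one metric."""
        col = self.table[metric].dropna().to_numpy()
        if col.size == 0:
            raise ValueError(f"metric {metric!r} not applicable for {self.method}")
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = col[(col >= lo_fence) & (col <= hi_fence)]
        return {
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(inliers.min()), "whisker_high": float(inliers.max()),
            "outliers": col[(col < lo_fence) | (col > hi_fence)].tolist(),
        }


def loocv(cohort: Sequence[PatientCase],
          predictor: OVHPredictorConfig | SVDLPredictorConfig) -> CohortEvaluation:
    """Leave-one-out cross validation of a predictor over a cohort.

    For each patient the model is refit on the other n-1 patients (OVH
    regression refit, or the distance-dose table and bin estimators rebuilt)
    and every metric the method supports is computed against the actual plan.
    Per-case distances and OVH features are computed once and reused across
    folds; the held-out patient's voxels never enter its own training pool.
    """
    n = len(cohort)
    if n < 3:
        raise LiverKBPError(f"LOOCV needs >= 3 patients, got {n}")
    ids = [c.case_id for c in cohort]
    if len(set(ids)) != n:
        raise LiverKBPError("case_ids must be unique within a cohort")
    threshold = predictor.threshold
    actual = [actual_v15(c, threshold) for c in cohort]
    rows = []
    if predictor.kind == "ovh":
        rv = [expansion_distance_at(compute_ovh(c), predictor.v) for c in cohort]
        v15 = [a.v15_normalized for a in actual]
        for i, case in enumerate(cohort):
            train_idx = [j for j in range(n) if j != i]
            model = fit_ovh_model([rv[j] for j in train_idx],
                                  [v15[j] for j in train_idx], v=predictor.v)
            pred = predict_v15(model, rv[i])
            rows.append({
                "case_id": case.case_id, "method": predictor.label,
                "actual_v15": v15[i], "predicted_v15": pred,
                "percent_error_v15": percent_error(v15[i], pred),
                "rss_dvh": np.nan, "mse_dose": np.nan,  # not applicable
            })
        meta = {"v": predictor.v, "threshold": threshold}
    else:
        per_case = [(case_distances(c), c.dose[c.oar_mask]) for c in cohort]
        scalar = predictor.method in SCALAR_METHODS
        for i, case in enumerate(cohort):
            train_cases = [cohort[j] for j in range(n) if j != i]
            train_pre = [per_case[j] for j in range(n) if j != i]
            table = build_distance_dose_table(train_cases, predictor.bin_width,
                                              precomputed=train_pre)
            seed = None if predictor.seed is None else predictor.seed + i
            est = estimate_bins(table, predictor.method,
                                resample_size=predictor.resample_size, rng=seed)
            dist_i, dose_i = per_case[i]
            pred_v15 = predict_v15_svdl(est, dist_i, threshold=threshold,
                                        dose_step=predictor.dose_step)
            dvh_a = actual_dvh(case, predictor.dose_step)
            dvh_p = predict_dvh(est, dist_i, predictor.dose_step,
                                dose_axis=dvh_a.dose_axis)
            row = {
                "case_id": case.case_id, "method": predictor.label,
                "actual_v15": actual[i].v15_normalized, "predicted_v15": pred_v15,
                "percent_error_v15": percent_error(actual[i].v15_normalized,
                                                   pred_v15),
                "rss_dvh": rss_dvh(dvh_a, dvh_p),
                "mse_dose": np.nan,
            }
            if scalar:
                pred_doses = predict_voxel_doses(est, dist_i)
                row["mse_dose"] = float(np.mean((dose_i - pred_doses) ** 2))
            rows.append(row)
        meta = {"method": predictor.method, "bin_width_mm": predictor.bin_width,
                "threshold": threshold, "dose_step_gy": predictor.dose_step}
    return CohortEvaluation(table=pd.DataFrame(rows), method=predictor.label,
                            metadata=meta)


def plot_percent_errors(evals: Sequence[CohortEvaluation], path: str,
                        metric: str = "percent_error_v15") -> None:
    """Render side-by-side boxplots of a metric for several evaluations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data, labels = [], []
    for ev in evals:
        col = ev.table[metric].dropna()
        if not col.empty:
            data.append(col.to_numpy())
            labels.append(ev.method)
    fig, ax = plt.subplots(figsize=(1.5 * max(len(data), 2) + 2, 4))
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
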