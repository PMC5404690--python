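"""Dose-volume prediction from the overlap volume histogram.

Across a training cohort, the expansion distance r_v at which a fraction v of
the liver overlaps the expanded target correlates with the normalized liver
volume receiving less than 15 Gy (V_<15Gy).  The model selects the v with the
strongest Pearson correlation (v = 10% in clinical cohorts), fits an ordinary
least-squares line V_<15Gy = slope * r_v + intercept, and predicts V_<15Gy
for a new patient from its r_v alone.  Per the capability matrix, this route
predicts the scalar V_<15Gy only — no DVH and no 3D dose.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cases import PatientCase
from .errors import DegenerateFitError

logger = logging.getLogger(__name__)

#: candidate overlap fractions screened for correlation with V_<15Gy
DEFAULT_CANDIDATE_V = (0.05, 0.10, 0.15, 0.20, 0.30)


@dataclass
class DoseVolumeMetric:
    """Liver volume receiving less than the threshold dose."""

    v15_normalized: float  # % of OAR volume
    v15_absolute: float    # cc


@dataclass
class OvhRegressionModel:
    """Linear model V_<15Gy [%] = slope * r_v [cm] + intercept."""

    v: float
    slope: float
    intercept: float
    pearson_r: float
    n_train: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "OvhRegressionModel":
        return cls(**json.loads(Path(path).read_text()))


def actual_v15(case: PatientCase, threshold: float = 15.0) -> DoseVolumeMetric:
    """Fraction of the OAR receiving strictly less than ``threshold`` Gy.

    Returned both normalized (% of OAR volume) and absolute (cc).  A minimum
    of 700 cc of liver spared from 15 Gy is the usual SBRT eligibility
    criterion this metric feeds.
    """
    doses = case.dose[case.oar_mask]
    frac = float(np.count_nonzero(doses < threshold)) / doses.size
    return DoseVolumeMetric(
        v15_normalized=100.0 * frac,
        v15_absolute=frac * case.oar_volume_cc,
    )


def select_best_v(cohort_rv: Mapping[float, Sequence[float]],
                  v15: Sequence[float]) -> tuple[float, dict[float, float]]:
    """Pick the overlap fraction whose r_v best correlates with V_<15Gy.

    Parameters
    ----------
    cohort_rv
        Mapping candidate v -> per-patient r_v (cm), all the same length.
    v15
        Per-patient normalized V_<15Gy (%).

    Returns
    -------
    (best_v, correlations)
        ``best_v`` maximizes \\|Pearson r\\|; ties break toward the smallest v.
        ``correlations`` reports the signed Pearson r of every usable
        candidate.  Zero-variance candidates are skipped with a warning.
    """
    if not cohort_rv:
        raise ValueError("empty candidate set")
    v15 = np.asarray(v15, dtype=np.float64)
    if v15.size < 3:
        raise ValueError("need at least 3 patients to correlate")
    correlations: dict[float, float] = {}
    for v in sorted(cohort_rv):
        rv = np.asarray(cohort_rv[v], dtype=np.float64)
        if rv.shape != v15.shape:
            raise ValueError(f"candidate v={v}: r_v length does not match v15")
        if np.std(rv) == 0.0:
            warnings.warn(f"candidate v={v} has zero-variance r_v; skipped")
            continue
        correlations[v] = float(stats.pearsonr(rv, v15).statistic)
    if not correlations:
        raise DegenerateFitError("every candidate r_v column has zero variance")
    best_v = max(sorted(correlations), key=lambda v: (abs(correlations[v]), -v))
    return best_v, correlations


def fit_ovh_model(rv: Sequence[float], v15: Sequence[float],
                  v: float = 0.10) -> OvhRegressionModel:
    """Ordinary least-squares fit of V_<15Gy [%] on r_v [cm]."""
    rv = np.asarray(rv, dtype=np.float64)
    v15 = np.asarray(v15, dtype=np.float64)
    if rv.shape != v15.shape or rv.ndim != 1:
        raise ValueError("rv and v15 must be matching 1D sequences")
    if rv.size < 3:
        raise DegenerateFitError(f"need >= 3 patients to fit, got {rv.size}")
    if np.std(rv) == 0.0:
        raise DegenerateFitError("r_v is constant across the cohort; slope undefined")
    res = stats.linregress(rv, v15)
    return OvhRegressionModel(
        v=v,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n_train=int(rv.size),
    )


def predict_v15(model: OvhRegressionModel, rv: float) -> float:
    """Predicted normalized V_<15Gy (%), clipped to the physical [0, 100]."""
    return float(np.clip(model.slope * rv + model.intercept, 0.0, 100.0))
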