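"""Statistical voxel dose learning (SVDL).

SVDL predicts a new patient's liver dose from the distances of its liver
voxels to the target.  Training liver voxels from prior plans are pooled and
sorted into bins by signed distance to the target boundary; the dose
histogram of each bin is then summarized one of five ways:

* scalar — ``median`` (preferred), ``mean`` or ``mode``: one dose value per
  bin, which supports per-voxel 3D dose prediction as well as DVH and
  V_<15Gy;
* ``skew_normal`` — a maximum-likelihood skew-normal fit (location xi,
  scale omega, shape alpha) per bin;
* ``non_parametric`` — each bin resampled by convolution with a Gaussian
  kernel to exactly 10,000 points, equalizing the statistical weight of
  sparsely populated bins near the target.

For the fitting methods a predicted DVH is the voxel-average survival
function of the per-bin distributions (a mixture model); they deliberately do
not commit to a single voxel dose, so 3D dose prediction is a capability
error for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .cases import DVHCurve, PatientCase, dvh_axis
from .errors import CapabilityError, CohortError
from .geometry import min_distance_to_target, signed_distance_field

logger = logging.getLogger(__name__)

Method = Literal["median", "mean", "mode", "skew_normal", "non_parametric"]

SCALAR_METHODS = ("median", "mean", "mode")
FITTING_METHODS = ("skew_normal", "non_parametric")

#: default bin width: one voxel at the standard 2.5 mm grid
DEFAULT_BIN_WIDTH_MM = 2.5
#: equal-size resample per bin for the non-parametric method
DEFAULT_RESAMPLE_SIZE = 10_000
#: bins with fewer samples than this fall back to the median for fitting methods
MIN_FIT_SAMPLES = 5
#: histogram granularity (Gy) for the mode estimator
MODE_BIN_GY = 0.5
#: default DVH dose resolution (Gy)
DEFAULT_DOSE_STEP_GY = 0.1


def case_distances(case: PatientCase) -> np.ndarray:
    """Signed distance (mm) from every OAR voxel to the target boundary."""
    fld = signed_distance_field(case.target_mask, case.spacing)
    return min_distance_to_target(case.oar_mask, fld)


@dataclass
class DistanceDoseTable:
    """Pooled (signed distance, dose) training samples, binned by distance.

    ``bins[i]`` holds the dose samples (Gy) of all training OAR voxels whose
    signed distance lies in ``[bin_edges[i], bin_edges[i+1])``.  Bin edges are
    aligned at 0 so liver voxels inside the target get their own bins.
    """

    bin_edges: np.ndarray
    bins: list[np.ndarray]
    n_patients: int

    @property
    def n_samples(self) -> int:
        return int(sum(b.size for b in self.bins))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def bin_index(self, distances: np.ndarray) -> np.ndarray:
        """Bin index per query distance, clamped to the edge bins."""
        idx = np.digitize(distances, self.bin_edges) - 1
        return np.clip(idx, 0, len(self.bins) - 1)


def build_distance_dose_table(
    training_cases: Sequence[PatientCase],
    bin_width: float = DEFAULT_BIN_WIDTH_MM,
    precomputed: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> DistanceDoseTable:
    """Pool every training OAR voxel's (distance, dose) pair into distance bins.

    Parameters
    ----------
    training_cases
        Cohort of patients with known dose.
    bin_width
        Bin width in mm (default one voxel, 2.5 mm), edges aligned at 0.
    precomputed
        Optional per-case ``(distances_mm, doses_gy)`` arrays, e.g. cached
        across cross-validation folds; must parallel ``training_cases``.
    """
    if len(training_cases) == 0:
        raise CohortError("cannot build a distance-dose table from an empty cohort")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if precomputed is None:
        precomputed = [
            (case_distances(c), c.dose[c.oar_mask]) for c in training_cases
        ]
    d = np.concatenate([p[0] for p in precomputed])
    dose = np.concatenate([p[1] for p in precomputed])
    lo = bin_width * np.floor(d.min() / bin_width)
    hi = bin_width * np.ceil(d.max() / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    order = np.argsort(idx, kind="stable")
    sorted_doses = dose[order]
    counts = np.bincount(idx, minlength=n_bins)
    splits = np.cumsum(counts)[:-1]
    bins = [np.ascontiguousarray(b) for b in np.split(sorted_doses, splits)]
    return DistanceDoseTable(bin_edges=edges, bins=bins,
                             n_patients=len(training_cases))


def _mode_estimate(samples: np.ndarray, bin_gy: float = MODE_BIN_GY) -> float:
    """Midpoint of the most populated dose-histogram bin."""
    lo = bin_gy * np.floor(samples.min() / bin_gy)
    hi = bin_gy * np.ceil(samples.max() / bin_gy)
    if hi <= lo:
        return float(samples[0])
    edges = np.arange(lo, hi + bin_gy / 2, bin_gy)
    counts, _ = np.histogram(samples, bins=edges)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def fit_skew_normal(samples: np.ndarray) -> tuple[float, float, float]:
    """MLE skew-normal fit returning (xi, omega, alpha).

    The skew-normal likelihood has singular Fisher information at alpha=0,
    which inflates alpha-hat and biases xi-hat on symmetric data.  The fit is
    therefore guarded by a likelihood-ratio comparison against the nested
    normal submodel: when the skewed fit does not improve the log-likelihood
    beyond the one-sided 5% chi-square point (2*dLL < 2.71), the normal MLE
    (mean, sd, alpha=0) is reported instead.
    """
    samples = np.asarray(samples, dtype=np.float64)
    mu, sd = float(samples.mean()), float(samples.std(ddof=0))
    if sd == 0.0:
        return mu, max(sd, 1e-12), 0.0
    with np.errstate(all="ignore"):
        a, loc, scale = stats.skewnorm.fit(samples)
        ll_skew = float(np.sum(stats.skewnorm.logpdf(samples, a, loc, scale)))
    ll_norm = float(np.sum(stats.norm.logpdf(samples, mu, sd)))
    if not np.isfinite(ll_skew) or 2.0 * (ll_skew - ll_norm) < 2.71:
        return mu, sd, 0.0
    return float(loc), float(scale), float(a)


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian kernel."""
    n = samples.size
    sd = samples.std(ddof=1) if n > 1 else 0.0
    if sd == 0.0:
        return 0.0
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    a = min(sd, iqr / 1.349) if iqr > 0 else sd
    return float(0.9 * a * n ** (-1 / 5))


def gaussian_kernel_resample(samples: np.ndarray, size: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Resample with replacement plus Gaussian kernel noise (KDE sampling).

    Doses are physical, so resampled points are reflected at 0 to stay
    non-negative.
    """
    h = silverman_bandwidth(samples)
    draw = rng.choice(samples, size=size, replace=True)
    if h > 0:
        draw = draw + rng.normal(0.0, h, size=size)
    return np.abs(draw)


@dataclass
class BinEstimatorSet:
    """Per-distance-bin dose-distribution summaries for one SVDL method.

    ``scalar`` holds one dose per bin for the scalar methods and for bins
    that fell back to the median under a fitting method; ``skew_params`` and
    ``resamples`` hold the fitting payloads.  ``fallback`` flags bins with
    too few samples for fitting.
    """

    method: Method
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    scalar: np.ndarray | None = None
    skew_params: np.ndarray | None = None      # (n_bins, 3): xi, omega, alpha
    resamples: list[np.ndarray | None] | None = None
    fallback: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def populated(self) -> np.ndarray:
        return self.bin_counts > 0

    def bin_index(self, distances: np.ndarray) -> np.ndarray:
        """Bin index per query distance, clamped to the nearest populated bin."""
        idx = np.clip(np.digitize(distances, self.bin_edges) - 1, 0, self.n_bins - 1)
        pop = np.flatnonzero(self.populated())
        if pop.size == 0:
            raise CohortError("estimator has no populated bins")
        if pop.size < self.n_bins:
            # snap each empty-bin query to the nearest populated bin
            nearest = pop[np.argmin(np.abs(idx[:, None] - pop[None, :]), axis=1)]
            idx = np.where(self.populated()[idx], idx, nearest)
        return idx


def estimate_bins(table: DistanceDoseTable, method: Method,
                  resample_size: int = DEFAULT_RESAMPLE_SIZE,
                  min_fit_samples: int = MIN_FIT_SAMPLES,
                  rng: np.random.Generator | int | None = None) -> BinEstimatorSet:
    """Summarize every populated distance bin with the chosen method.

    Fitting methods (skew_normal, non_parametric) fall back to the bin median
    when a bin holds fewer than ``min_fit_samples`` samples; the fallback is
    logged and flagged.  ``rng`` seeds the non-parametric resampling.
    """
    if method not in SCALAR_METHODS + FITTING_METHODS:
        raise ValueError(f"unknown SVDL method {method!r}")
    if table.n_samples == 0:
        raise CohortError("distance-dose table is empty")
    rng = np.random.default_rng(rng)
    n_bins = len(table.bins)
    counts = np.array([b.size for b in table.bins])
    est = BinEstimatorSet(method=method, bin_edges=table.bin_edges.copy(),
                          bin_counts=counts)
    scalar = np.full(n_bins, np.nan)
    fallback = np.zeros(n_bins, dtype=bool)
    if method in SCALAR_METHODS:
        fn = {"median": np.median, "mean": np.mean, "mode": _mode_estimate}[method]
        for i, b in enumerate(table.bins):
            if b.size:
                scalar[i] = fn(b)
        est.scalar = scalar
        return est
    if method == "skew_normal":
        params = np.full((n_bins, 3), np.nan)
        for i, b in enumerate(table.bins):
            if b.size == 0:
                continue
            if b.size < min_fit_samples:
                scalar[i] = np.median(b)
                fallback[i] = True
                logger.info("bin %d: %d samples < %d, falling back to median",
                            i, b.size, min_fit_samples)
                continue
            params[i] = fit_skew_normal(b)
        est.skew_params = params
    else:  # non_parametric
        resamples: list[np.ndarray | None] = [None] * n_bins
        for i, b in enumerate(table.bins):
            if b.size == 0:
                continue
            if b.size < min_fit_samples:
                scalar[i] = np.median(b)
                fallback[i] = True
                logger.info("bin %d: %d samples < %d, falling back to median",
                            i, b.size, min_fit_samples)
                continue
            resamples[i] = gaussian_kernel_resample(b, resample_size, rng)
        est.resamples = resamples
    est.scalar = scalar
    est.fallback = fallback
    return est


def predict_voxel_doses(est: BinEstimatorSet, distances: np.ndarray) -> np.ndarray:
    """Per-voxel predicted dose (scalar methods) or bin reference (fitting).

    Scalar methods return one dose (Gy) per query voxel.  Fitting methods do
    not commit to a voxel dose; they return each voxel's distance-bin index,
    the handle into the per-bin distributions used by :func:`predict_dvh`.
    Out-of-range distances clamp to the nearest populated bin.
    """
    distances = np.asarray(distances, dtype=np.float64)
    idx = est.bin_index(distances)
    if est.method in SCALAR_METHODS:
        return est.scalar[idx]
    return idx


def _bin_survival(est: BinEstimatorSet, i: int, dose_axis: np.ndarray) -> np.ndarray:
    """P(dose >= D) along the axis under bin i's fitted distribution."""
    if est.fallback is not None and est.fallback[i]:
        return (est.scalar[i] >= dose_axis).astype(float)
    if est.method == "skew_normal":
        xi, omega, alpha = est.skew_params[i]
        return stats.skewnorm.sf(dose_axis, alpha, loc=xi, scale=omega)
    sample = np.sort(est.resamples[i])
    return 1.0 - np.searchsorted(sample, dose_axis, side="left") / sample.size


def predict_dvh(est: BinEstimatorSet, distances: np.ndarray,
                dose_step: float = DEFAULT_DOSE_STEP_GY,
                dose_axis: np.ndarray | None = None) -> DVHCurve:
    """Predicted cumulative DVH for a query patient's OAR voxels.

    Scalar methods: the empirical DVH of the predicted per-voxel doses.
    Fitting methods: DVH(D) = mean over voxels of P(dose >= D) under each
    voxel's bin distribution — the survival function of the per-voxel mixture.
    """
    distances = np.asarray(distances, dtype=np.float64)
    idx = est.bin_index(distances)
    if est.method in SCALAR_METHODS:
        doses = est.scalar[idx]
        if dose_axis is None:
            dose_axis = dvh_axis(float(doses.max()), dose_step)
        from .cases import dvh_from_doses
        return dvh_from_doses(doses, dose_step, dose_axis)
    weights = np.bincount(idx, minlength=est.n_bins).astype(float)
    weights /= weights.sum()
    used = np.flatnonzero(weights > 0)
    if dose_axis is None:
        top = 0.0
        for i in used:
            if est.fallback is not None and est.fallback[i]:
                top = max(top, float(est.scalar[i]))
            elif est.method == "skew_normal":
                xi, omega, alpha = est.skew_params[i]
                top = max(top, float(stats.skewnorm.ppf(0.9999, alpha, loc=xi,
                                                        scale=omega)))
            else:
                top = max(top, float(est.resamples[i].max()))
        dose_axis = dvh_axis(top, dose_step)
    dose_axis = np.asarray(dose_axis, dtype=np.float64)
    dvh = np.zeros_like(dose_axis)
    for i in used:
        dvh += weights[i] * _bin_survival(est, i, dose_axis)
    dvh = np.clip(dvh, 0.0, 1.0)
    dvh[0] = 1.0  # physical doses are non-negative: everything gets >= 0 Gy
    dvh = np.minimum.accumulate(dvh)
    return DVHCurve(dose_axis=dose_axis, volume_fraction=dvh)


def predict_v15_svdl(est: BinEstimatorSet, distances: np.ndarray,
                     threshold: float = 15.0,
                     dose_step: float = DEFAULT_DOSE_STEP_GY) -> float:
    """Predicted normalized V_<15Gy (%) = 100 * (1 - DVH(threshold))."""
    distances = np.asarray(distances, dtype=np.float64)
    if est.method in SCALAR_METHODS:
        doses = predict_voxel_doses(est, distances)
        return 100.0 * float(np.count_nonzero(doses < threshold)) / doses.size
    # make sure the threshold is an exact axis point
    top = max(threshold * 2, 80.0)
    n = int(round(top / dose_step))
    axis = np.arange(n + 1) * dose_step
    dvh = predict_dvh(est, distances, dose_step, dose_axis=axis)
    return 100.0 * (1.0 - dvh.at(threshold))


def predict_dose_3d(est: BinEstimatorSet, case_geometry: PatientCase) -> np.ndarray:
    """Predicted 3D dose on the OAR voxels of a query case (scalar methods).

    Voxels outside the OAR are NaN (dose is only defined within the liver).
    Fitting methods cannot produce a unique per-voxel dose and raise
    :class:`CapabilityError`.
    """
    if est.method not in SCALAR_METHODS:
        raise CapabilityError(
            f"3D dose prediction requires a scalar SVDL method "
            f"(median/mean/mode); {est.method!r} predicts V_<15Gy and DVH only"
        )
    distances = case_distances(case_geometry)
    doses = predict_voxel_doses(est, distances)
    grid = np.full(case_geometry.oar_mask.shape, np.nan)
    grid[case_geometry.oar_mask] = doses
    return grid
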