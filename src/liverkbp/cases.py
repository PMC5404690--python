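"""Core data containers: per-patient voxel data and DVH curves.

A :class:`PatientCase` bundles everything the dose-prediction models need for
one patient/plan: an organ-at-risk (liver) mask, a target (PTV) mask and a
dose grid, all voxelized on one common 3D grid, plus the grid spacing and the
prescription dose.  Masks and dose must share a single shape; the models
never resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, GeometryError

PLAN_STYLES = ("isotropic-like", "coplanar-like", "clinical-unknown")


@dataclass
class PatientCase:
    """Voxelized data for a single patient/plan on a common grid.

    Parameters
    ----------
    case_id
        Unique identifier within a cohort.
    oar_mask, target_mask
        Boolean grids for the organ at risk (liver) and the planning target
        volume.  Both must be non-empty and share the dose grid's shape.
    dose
        Planned dose in Gy, non-negative.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm; all components positive.
    prescription
        Prescription dose in Gy.
    plan_style
        Free tag recording how the plan's fall-off behaves:
        ``isotropic-like`` (4pi-style), ``coplanar-like`` (VMAT-style) or
        ``clinical-unknown``.
    """

    case_id: str
    oar_mask: np.ndarray
    target_mask: np.ndarray
    dose: np.ndarray
    spacing: tuple[float, float, float]
    prescription: float
    plan_style: str = "clinical-unknown"

    def __post_init__(self) -> None:
        self.oar_mask = np.asarray(self.oar_mask, dtype=bool)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        self.dose = np.asarray(self.dose, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        if not (self.oar_mask.shape == self.target_mask.shape == self.dose.shape):
            raise DimensionError(
                f"case {self.case_id!r}: oar/target/dose grids must share one "
                f"shape, got {self.oar_mask.shape}, {self.target_mask.shape}, "
                f"{self.dose.shape}"
            )
        if self.oar_mask.ndim != 3:
            raise DimensionError(f"case {self.case_id!r}: grids must be 3D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"case {self.case_id!r}: spacing must be 3 positive mm values")
        if not self.oar_mask.any():
            raise GeometryError(f"case {self.case_id!r}: empty OAR mask")
        if not self.target_mask.any():
            raise GeometryError(f"case {self.case_id!r}: empty target mask")
        if np.any(self.dose < 0):
            raise GeometryError(f"case {self.case_id!r}: dose must be non-negative")
        if self.plan_style not in PLAN_STYLES:
            raise ValueError(f"plan_style must be one of {PLAN_STYLES}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def oar_volume_cc(self) -> float:
        """OAR volume in cc (voxel count times voxel volume)."""
        return float(self.oar_mask.sum()) * self.voxel_volume_mm3 / 1000.0

    @property
    def target_volume_cc(self) -> float:
        return float(self.target_mask.sum()) * self.voxel_volume_mm3 / 1000.0


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``volume_fraction[i]`` is the fraction of the OAR receiving a dose of at
    least ``dose_axis[i]`` Gy.  The curve starts at 1 at D=0, is monotone
    non-increasing, and reaches 0 at or above the maximum dose.
    """

    dose_axis: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=np.float64)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=np.float64)
        if self.dose_axis.shape != self.volume_fraction.shape or self.dose_axis.ndim != 1:
            raise DimensionError("dose_axis and volume_fraction must be matching 1D arrays")
        if len(self.dose_axis) >= 2 and np.any(np.diff(self.dose_axis) <= 0):
            raise ValueError("dose_axis must be strictly increasing")

    @property
    def dose_step(self) -> float:
        return float(self.dose_axis[1] - self.dose_axis[0])

    def at(self, dose_gy: float) -> float:
        """Volume fraction at a dose level, linearly interpolated."""
        return float(np.interp(dose_gy, self.dose_axis, self.volume_fraction))


def dvh_axis(max_dose: float, dose_step: float) -> np.ndarray:
    """Uniform dose axis from 0 to just above ``max_dose`` (inclusive 0)."""
    n = int(np.ceil(max_dose / dose_step)) + 2
    return np.arange(n) * dose_step


def dvh_from_doses(doses: np.ndarray, dose_step: float = 0.1,
                   dose_axis: np.ndarray | None = None) -> DVHCurve:
    """Empirical cumulative DVH of a set of voxel doses.

    ``DVH(D)`` is the fraction of voxels with dose >= D.
    """
    doses = np.asarray(doses, dtype=np.float64)
    if doses.size == 0:
        raise ValueError("need at least one voxel dose")
    if dose_axis is None:
        dose_axis = dvh_axis(float(doses.max()), dose_step)
    # fraction >= D via a sorted search: count of doses < D, complemented
    order = np.sort(doses)
    below = np.searchsorted(order, dose_axis, side="left")
    frac = 1.0 - below / doses.size
    return DVHCurve(dose_axis=np.asarray(dose_axis, float), volume_fraction=frac)


def actual_dvh(case: PatientCase, dose_step: float = 0.1,
               dose_axis: np.ndarray | None = None) -> DVHCurve:
    """DVH of the planned dose over the case's OAR voxels."""
    return dvh_from_doses(case.dose[case.oar_mask], dose_step, dose_axis)
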