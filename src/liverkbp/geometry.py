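"""Voxel-grid geometry: signed distance fields and overlap volume histograms.

The overlap volume histogram (OVH) of an organ at risk (OAR) with respect to
a target T is

    OVH(r) = |{p in OAR : d(p, T) <= r}| / |OAR|,

where d(p, T) is the signed Euclidean distance from voxel p to the target
boundary (negative strictly inside the target, zero on boundary voxels,
positive outside).  Expanding the target isotropically by r and measuring the
fractional OAR overlap gives the same curve; when OAR and target overlap the
target must be "contracted" (negative r) before the curve reaches zero.

Conventions
-----------
* The target boundary is the set of target voxels with at least one
  face-adjacent non-target neighbour (grid edges count as outside).
* Distances are voxel-centre to voxel-centre, in mm, with anisotropic
  spacing respected.  OVH distances are exposed in cm.
* Per-voxel distance lists follow C-order (row-major) traversal of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cases import PatientCase
from .errors import DimensionError, GeometryError

#: default OVH sampling step in cm — one voxel at the standard 2.5 mm grid
DEFAULT_R_STEP_CM = 0.25


@dataclass
class DistanceField:
    """Signed distance (mm) to the target boundary for every grid voxel.

    Negative strictly inside the target, zero on boundary voxels, positive
    outside.
    """

    values: np.ndarray
    domain_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.domain_mask.shape:
            raise DimensionError("values and domain_mask must share a shape")


@dataclass
class OVHCurve:
    """Sampled overlap volume histogram: fractional OAR overlap vs r (cm)."""

    r_values: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=np.float64)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.r_values.shape != self.fractions.shape or self.r_values.ndim != 1:
            raise DimensionError("r_values and fractions must be matching 1D arrays")
        if np.any(np.diff(self.r_values) <= 0):
            raise ValueError("r_values must be strictly increasing")
        if np.any(np.diff(self.fractions) < 0):
            raise ValueError("fractions must be non-decreasing")
        if self.fractions.min() < 0 or self.fractions.max() > 1:
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def is_complete(self) -> bool:
        """True when the sampled curve spans fractions 0 through 1."""
        return bool(self.fractions[0] == 0.0 and self.fractions[-1] == 1.0)


def target_boundary(target_mask: np.ndarray) -> np.ndarray:
    """Target voxels with >= 1 face-adjacent non-target neighbour.

    Voxels on the grid edge count as boundary (outside the grid is outside
    the target).
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(target_mask, structure=structure, border_value=0)
    return target_mask & ~interior


def signed_distance_field(target_mask: np.ndarray,
                          spacing: tuple[float, float, float]) -> DistanceField:
    """Signed Euclidean distance from every voxel centre to the target boundary.

    |value| is the minimal centre-to-centre distance (mm) to a boundary voxel;
    the sign is negative strictly inside the target and positive outside.

    Raises
    ------
    GeometryError
        If the target mask is empty or fills the whole grid (no boundary
        exterior exists in the latter case under the all-inside convention
        rejected here for lack of an outside).
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if target_mask.ndim != 3:
        raise DimensionError("target_mask must be 3D")
    if not target_mask.any():
        raise GeometryError("target mask is empty")
    if target_mask.all():
        raise GeometryError("target mask fills the entire grid")
    boundary = target_boundary(target_mask)
    # distance from every voxel to the nearest boundary-voxel centre
    dist = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    sign = np.where(target_mask & ~boundary, -1.0, 1.0)
    return DistanceField(values=dist * sign, domain_mask=np.ones_like(target_mask))


def min_distance_to_target(oar_mask: np.ndarray, field: DistanceField) -> np.ndarray:
    """Signed distance (mm) for each OAR voxel, in C-order traversal.

    This is the per-voxel m(p, T) = min_{t in boundary(T)} |p - t|, signed.
    """
    oar_mask = np.asarray(oar_mask, dtype=bool)
    if oar_mask.shape != field.values.shape:
        raise DimensionError(
            f"OAR mask shape {oar_mask.shape} does not match distance field "
            f"shape {field.values.shape}"
        )
    return field.values[oar_mask]


def brute_force_signed_distances(target_mask: np.ndarray,
                                 spacing: tuple[float, float, float]) -> np.ndarray:
    """Exhaustive pairwise-minimum signed distances; O(N * |boundary|).

    Test oracle only — exact but unusable beyond small grids.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if not target_mask.any() or target_mask.all():
        raise GeometryError("degenerate target mask")
    boundary = target_boundary(target_mask)
    bcoords = np.argwhere(boundary) * np.asarray(spacing, float)
    coords = np.indices(target_mask.shape).reshape(3, -1).T * np.asarray(spacing, float)
    out = np.empty(coords.shape[0])
    for i, c in enumerate(coords):
        out[i] = np.sqrt(((bcoords - c) ** 2).sum(axis=1)).min()
    out = out.reshape(target_mask.shape)
    sign = np.where(target_mask & ~boundary, -1.0, 1.0)
    return out * sign


def compute_ovh(case: PatientCase, r_grid: np.ndarray | None = None,
                r_step_cm: float = DEFAULT_R_STEP_CM) -> OVHCurve:
    """Overlap volume histogram of the case's OAR with respect to its target.

    The curve is sampled on a uniform r grid (cm).  When ``r_grid`` is not
    given, the grid uses ``r_step_cm`` spacing and is extended until the
    fractions reach exactly 0 at the low end and 1 at the high end, so the
    curve is always complete.
    """
    field = signed_distance_field(case.target_mask, case.spacing)
    d_cm = min_distance_to_target(case.oar_mask, field) / 10.0  # mm -> cm
    if r_grid is None:
        lo = r_step_cm * np.floor(d_cm.min() / r_step_cm) - r_step_cm
        hi = r_step_cm * np.ceil(d_cm.max() / r_step_cm)
        if hi <= lo:
            hi = lo + r_step_cm
        n = int(round((hi - lo) / r_step_cm)) + 1
        r_grid = lo + r_step_cm * np.arange(n)
    r_grid = np.asarray(r_grid, dtype=np.float64)
    fractions = np.searchsorted(np.sort(d_cm), r_grid, side="right") / d_cm.size
    return OVHCurve(r_values=r_grid, fractions=fractions)


def expansion_distance_at(ovh: OVHCurve, v: float) -> float:
    """r_v: the smallest expansion distance (cm) at which OVH(r) >= v.

    Linear interpolation between sampled points; for a saturated curve
    (fraction already >= v at the first sample) the first sampled r is
    returned.

    Raises
    ------
    ValueError
        If v is outside the open interval (0, 1).
    """
    if not 0.0 < v < 1.0:
        raise ValueError(f"overlap fraction v must be in (0, 1), got {v}")
    f = ovh.fractions
    r = ovh.r_values
    idx = int(np.searchsorted(f, v, side="left"))
    if idx >= len(f):
        raise ValueError("OVH curve is incomplete: never reaches the requested fraction")
    if idx == 0:
        return float(r[0])
    f0, f1 = f[idx - 1], f[idx]
    r0, r1 = r[idx - 1], r[idx]
    if f1 == f0:
        return float(r1)
    return float(r0 + (v - f0) * (r1 - r0) / (f1 - f0))
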