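"""Synthetic phantom cohorts for exercising the dose-prediction models.

Each phantom is an ellipsoidal liver containing (or abutting) a spherical
planning target, on a uniform voxel grid, with a dose field that decays
smoothly with the (optionally direction-scaled) signed distance to the
target:

    dose(p) = prescription * s(m_aniso(p) / falloff_scale) * (1 + eps_p)

where s is a normalized logistic fall-off with s(d <= 0) = 1, m_aniso is the
signed distance computed with per-axis spacing multipliers, and eps_p is
multiplicative Gaussian voxel noise.  Isotropic mode (all multipliers 1)
mimics non-coplanar plans whose dose is nearly a pure function of distance
to the target; anisotropic mode makes the fall-off systematically steeper
along one axis, mimicking the stronger superior/inferior gradient of
coplanar arc plans — which widens the per-distance-bin dose spread exactly
as real coplanar cohorts do.

Population defaults follow the clinical cohort being emulated: liver
volumes 550-3346 cc, target volumes 2-222 cc, prescriptions 30-60 Gy.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .cases import PatientCase
from .errors import GeometryError
from .geometry import signed_distance_field

#: clinical ranges of the emulated cohort
LIVER_VOLUME_RANGE_CC = (550.0, 3346.0)
PTV_VOLUME_RANGE_CC = (2.0, 222.0)
PRESCRIPTION_RANGE_GY = (30.0, 60.0)

DEFAULT_SPACING = (2.5, 2.5, 2.5)


def ellipsoid_semi_axes(volume_cc: float,
                        ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
                        ) -> tuple[float, float, float]:
    """Semi-axes (mm) of an ellipsoid with the given volume and axis ratios."""
    volume_mm3 = volume_cc * 1000.0
    r3 = volume_mm3 * 3.0 / (4.0 * math.pi * ratios[0] * ratios[1] * ratios[2])
    r = r3 ** (1.0 / 3.0)
    return tuple(r * q for q in ratios)


def sphere_radius(volume_cc: float) -> float:
    """Radius (mm) of a sphere with the given volume."""
    return (volume_cc * 1000.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class PhantomSpec:
    """Full recipe for one phantom; identical specs generate identical cases.

    All geometry is in mm, in grid coordinates (voxel centre of index i along
    axis a sits at i * spacing[a]).
    """

    case_id: str
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    liver_semi_axes: tuple[float, float, float] = (70.0, 70.0, 70.0)
    liver_center: tuple[float, float, float] | None = None
    ptv_radius: float = 15.0
    ptv_center: tuple[float, float, float] | None = None
    prescription: float = 50.0
    falloff_scale: float = 10.0
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    falloff_k: float = 4.0
    falloff_x0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.falloff_scale <= 0:
            raise ValueError("falloff_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(a <= 0 for a in self.anisotropy):
            raise ValueError("anisotropy multipliers must be positive")
        if self.liver_center is None:
            self.liver_center = tuple(
                (s - 1) * sp / 2.0 for s, sp in zip(self.shape, self.spacing))
        if self.ptv_center is None:
            self.ptv_center = self.liver_center

    @property
    def liver_volume_cc(self) -> float:
        a, b, c = self.liver_semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for k in ("shape", "spacing", "liver_semi_axes", "liver_center",
                  "ptv_center", "anisotropy"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def dose_falloff(x: np.ndarray, k: float = 4.0, x0: float = 1.0) -> np.ndarray:
    """Normalized logistic fall-off: 1 for x <= 0, smoothly decaying after.

    s(x) = sigmoid(k*(x0 - x)) / sigmoid(k*x0), so s(0) = 1 exactly and s is
    monotone decreasing to 0.
    """
    x = np.asarray(x, dtype=np.float64)
    norm = 1.0 / (1.0 + np.exp(-k * x0))
    s = 1.0 / (1.0 + np.exp(-k * (x0 - x))) / norm
    return np.where(x <= 0.0, 1.0, s)


def _voxel_coords(shape: tuple[int, int, int],
                  spacing: tuple[float, float, float]) -> list[np.ndarray]:
    return [np.arange(n) * sp for n, sp in zip(shape, spacing)]


def generate_phantom(spec: PhantomSpec) -> PatientCase:
    """Realize a PhantomSpec into a PatientCase (deterministic given seed)."""
    xs = _voxel_coords(spec.shape, spec.spacing)
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    lc, la = spec.liver_center, spec.liver_semi_axes
    liver = (((gx - lc[0]) / la[0]) ** 2 + ((gy - lc[1]) / la[1]) ** 2
             + ((gz - lc[2]) / la[2]) ** 2) <= 1.0
    pc, pr = spec.ptv_center, spec.ptv_radius
    extent = [(n - 1) * sp for n, sp in zip(spec.shape, spec.spacing)]
    if any(pc[a] - pr < 0 or pc[a] + pr > extent[a] for a in range(3)):
        raise GeometryError(
            f"{spec.case_id}: PTV (center {pc}, radius {pr} mm) does not fit "
            f"inside the grid extent {extent} mm")
    ptv = ((gx - pc[0]) ** 2 + (gy - pc[1]) ** 2 + (gz - pc[2]) ** 2) <= pr ** 2
    if not ptv.any():
        raise GeometryError(f"{spec.case_id}: PTV sphere contains no voxel")

    scaled_spacing = tuple(sp * m for sp, m in zip(spec.spacing, spec.anisotropy))
    d_aniso = signed_distance_field(ptv, scaled_spacing).values
    dose = spec.prescription * dose_falloff(
        d_aniso / spec.falloff_scale, spec.falloff_k, spec.falloff_x0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dose = dose * (1.0 + rng.normal(0.0, spec.noise_sd, size=dose.shape))
    dose = np.clip(dose, 0.0, None)
    dose[ptv] = np.maximum(dose[ptv], spec.prescription)

    style = "isotropic-like" if all(m == spec.anisotropy[0]
                                    for m in spec.anisotropy) else "coplanar-like"
    return PatientCase(
        case_id=spec.case_id, oar_mask=liver, target_mask=ptv, dose=dose,
        spacing=spec.spacing, prescription=spec.prescription, plan_style=style)


@dataclass
class CohortPopulation:
    """Population distributions for cohort drawing (clinical defaults).

    Liver volumes are drawn uniformly over the clinical range; target
    volumes log-uniformly (clinical target volumes skew small); prescriptions
    uniformly.  Per-patient fall-off scales are uniform over
    ``falloff_range`` — this inter-patient variability is what makes
    leave-one-out errors non-zero.
    """

    liver_volume_range: tuple[float, float] = LIVER_VOLUME_RANGE_CC
    ptv_volume_range: tuple[float, float] = PTV_VOLUME_RANGE_CC
    prescription_range: tuple[float, float] = PRESCRIPTION_RANGE_GY
    falloff_range: tuple[float, float] = (8.0, 12.0)
    noise_sd: float = 0.05
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    axis_ratio_range: tuple[float, float] = (0.8, 1.25)
    ptv_offset_fraction: float = 0.5
    anisotropy_z_range: tuple[float, float] = (1.6, 2.4)
    anisotropy_xy_range: tuple[float, float] = (0.9, 1.1)
    margin_mm: float = 7.5

    def __post_init__(self) -> None:
        for rng_ in (self.liver_volume_range, self.ptv_volume_range,
                     self.prescription_range, self.falloff_range):
            if rng_[0] > rng_[1] or rng_[0] <= 0:
                raise ValueError(f"infeasible population range {rng_}")


def draw_phantom_spec(rng: np.random.Generator, case_id: str,
                      mode: str = "isotropic",
                      population: CohortPopulation | None = None) -> PhantomSpec:
    """Draw one phantom recipe from the population distributions.

    Draws happen in a fixed order, with the anisotropy multipliers consumed
    last and unconditionally, so cohorts generated in isotropic and
    anisotropic mode from the same seed are matched pairs — identical
    geometry, prescriptions, fall-off scales and noise, differing only in
    the directional scaling of the dose fall-off.  That matched design is
    what makes mode comparisons "at equal noise" meaningful.
    """
    pop = population or CohortPopulation()
    liver_cc = rng.uniform(*pop.liver_volume_range)
    ratios = rng.uniform(*pop.axis_ratio_range, size=3)
    ratios /= ratios.prod() ** (1.0 / 3.0)
    semi = ellipsoid_semi_axes(liver_cc, tuple(ratios))
    ptv_cc = math.exp(rng.uniform(math.log(pop.ptv_volume_range[0]),
                                  math.log(pop.ptv_volume_range[1])))
    pr = sphere_radius(ptv_cc)
    # random PTV offset inside the liver, scaled so the sphere stays inside
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    frac = rng.uniform(0.0, pop.ptv_offset_fraction)
    offset = np.array([frac * max(semi[a] - pr, 0.0) * u[a] for a in range(3)])
    prescription = float(rng.uniform(*pop.prescription_range))
    falloff = float(rng.uniform(*pop.falloff_range))
    noise_seed = int(rng.integers(0, 2**31 - 1))
    aniso_draw = (rng.uniform(*pop.anisotropy_xy_range),
                  rng.uniform(*pop.anisotropy_xy_range),
                  rng.uniform(*pop.anisotropy_z_range))

    if mode == "isotropic":
        aniso = (1.0, 1.0, 1.0)
    elif mode == "anisotropic":
        aniso = aniso_draw
    else:
        raise ValueError(f"unknown cohort mode {mode!r}")

    sp = pop.spacing
    half = [semi[a] + max(pr - semi[a], 0.0) + pop.margin_mm for a in range(3)]
    shape = tuple(int(np.ceil(2 * half[a] / sp[a])) + 1 for a in range(3))
    center = tuple((shape[a] - 1) * sp[a] / 2.0 for a in range(3))

    return PhantomSpec(
        case_id=case_id, shape=shape, spacing=sp,
        liver_semi_axes=tuple(semi), liver_center=center,
        ptv_radius=pr, ptv_center=tuple(np.asarray(center) + offset),
        prescription=prescription,
        falloff_scale=falloff,
        anisotropy=tuple(float(a) for a in aniso),
        noise_sd=pop.noise_sd,
        seed=noise_seed,
    )


def generate_cohort(n: int, mode: str = "isotropic", seed: int = 0,
                    population: CohortPopulation | None = None,
                    ) -> tuple[list[PatientCase], list[PhantomSpec]]:
    """Draw and realize a cohort of n phantoms; reproducible given seed.

    Each patient draws from its own child generator, so cohorts are stable
    under extension (the first k patients of an n-cohort equal the k-cohort)
    and isotropic/anisotropic cohorts with the same seed are matched pairs.
    Returns the cases together with the full per-patient specs so a cohort
    can be replayed or serialized exactly.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    master = np.random.default_rng(seed)
    child_seeds = [int(master.integers(0, 2**31 - 1)) for _ in range(n)]
    specs = [draw_phantom_spec(np.random.default_rng(s),
                               f"phantom-{i:03d}", mode, population)
             for i, s in enumerate(child_seeds)]
    cases = [generate_phantom(s) for s in specs]
    return cases, specs
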