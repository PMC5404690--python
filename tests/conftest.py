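import numpy as np
import pytest

from liverkbp import PatientCase, CohortPopulation, generate_cohort


@pytest.fixture
def box_case() -> PatientCase:
    """Hand-built case: 3x3x3 target block inside a 14^3 grid, box liver.

    Dose is a pure function of signed distance to the target, making every
    downstream quantity checkable by enumeration.
    """
    shape = (14, 14, 14)
    target = np.zeros(shape, bool)
    target[5:8, 5:8, 5:8] = True
    liver = np.zeros(shape, bool)
    liver[2:12, 2:12, 2:12] = True
    from liverkbp import signed_distance_field
    d = signed_distance_field(target, (2.5, 2.5, 2.5)).values
    dose = 50.0 * np.exp(-np.maximum(d, 0.0) / 12.0)
    return PatientCase(case_id="box", oar_mask=liver, target_mask=target,
                       dose=dose, spacing=(2.5, 2.5, 2.5), prescription=50.0)


@pytest.fixture(scope="session")
def coarse_population() -> CohortPopulation:
    """Clinical population at 5 mm voxels — fast enough for unit tests."""
    return CohortPopulation(spacing=(5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def small_cohort(coarse_population):
    """Five modest phantoms with noise, for harness-level tests."""
    pop = CohortPopulation(spacing=(5.0, 5.0, 5.0),
                           liver_volume_range=(550.0, 1200.0))
    cases, specs = generate_cohort(5, "isotropic", seed=11, population=pop)
    return cases, specs
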