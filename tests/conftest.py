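import numpy as np
import pytest

from nactwin.calibration import CaseGeometry
from nactwin.cohort import clinical_cohort
from nactwin.domain import build_sphere_domain, place_seed
from nactwin.kinetics import DrugParams, ModelParams
from nactwin.solver import DiffusionOperator


@pytest.fixture(scope="session")
def small_domain():
    """A ~14 cm^3 spherical ROI at 1.5 mm spacing (a few thousand voxels)."""
    return build_sphere_domain(radius_mm=15.0, spacing_mm=1.5)


@pytest.fixture(scope="session")
def small_operator(small_domain):
    return DiffusionOperator(small_domain)


@pytest.fixture(scope="session")
def seeded_small(small_domain):
    field, v_i = place_seed(small_domain, small_domain.center_index, 0.5, 0.01)
    return field, v_i


@pytest.fixture(scope="session")
def cohort():
    return clinical_cohort()


@pytest.fixture(scope="session")
def cohort_by_id(cohort):
    return {case.id: (case, params) for case, params in cohort}


@pytest.fixture()
def single_drug_params():
    return ModelParams(
        r_c=4.0e-7,
        drugs=(DrugParams(name="EC", eps_pd=3.64e-6, eps_pk_per_hour=2.0),),
    )


@pytest.fixture(scope="session")
def coarse_geometry_factory():
    """Small-geometry factory for calibration tests (keeps suites quick)."""

    def make(v0_cm3: float) -> CaseGeometry:
        return CaseGeometry.for_case(v0_cm3, target_voxels=2500)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
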