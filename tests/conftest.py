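import numpy as np
import pytest

from neckssm import CohortSpec, NeckGenParams, generate_cohort, generate_neck, parametrize
from neckssm.correspond import ShapeCohort, process_grid

#: coarse but valid mesh resolution for fast tests
SMALL = dict(axial_samples=12, circumferential_samples=36)


@pytest.fixture(scope="session")
def cylinder_params():
    return NeckGenParams(baseline_diameter=24.0, length=30.0, **SMALL)


@pytest.fixture(scope="session")
def cylinder(cylinder_params):
    return generate_neck(cylinder_params, seed=0)


@pytest.fixture(scope="session")
def cone_params():
    return NeckGenParams(baseline_diameter=24.0, length=30.0, taper=0.10, **SMALL)


@pytest.fixture(scope="session")
def cone(cone_params):
    return generate_neck(cone_params, seed=0)


@pytest.fixture(scope="session")
def bowed_params():
    return NeckGenParams(bow_lr=4.0, bow_ant=2.0, distal_tilt=5.0, **SMALL)


@pytest.fixture(scope="session")
def noisy_params():
    return NeckGenParams(bow_lr=3.0, noise_sd=0.3, **SMALL)


def small_cohort_spec(n=12, seed=0, **kw):
    defaults = dict(
        n=n,
        mean_params=NeckGenParams(**SMALL),
        seed=seed,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """Parametrized 12-patient synthetic cohort at coarse mesh resolution."""
    necks, truth = generate_cohort(small_cohort_spec(n=12, seed=42))
    rows = [process_grid(parametrize(nk.mesh, nk.cll, nk.landmarks)) for nk in necks]
    cohort = ShapeCohort([f"P{i:02d}" for i in range(len(rows))], np.vstack(rows))
    return cohort, truth
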