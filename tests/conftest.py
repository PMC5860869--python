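import numpy as np
import pytest

from topofc.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(
        n_subjects=24,
        n_grayordinates=400,
        n_modes=5,
        n_timepoints=150,
        n_behaviour=12,
        n_confounds=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
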