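import numpy as np
import pytest

from strainspec import (
    CohortConfig,
    WavelengthGrid,
    cap_vectors_per_patient,
    composites_from_table,
    generate_archetypes,
    generate_cohort_dataset,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def archetypes():
    return generate_archetypes(3, seed=1)


@pytest.fixture(scope="session")
def small_dataset(archetypes):
    config = CohortConfig(
        patients_per_cohort={"DS": 4, "AD": 4, "ADNC": 4},
        plaques_per_patient=(6, 12),
        noise_sd=0.05,
        seed=11,
    )
    return generate_cohort_dataset(config, archetypes)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return composites_from_table(small_dataset.spectra_table, seed=3)


@pytest.fixture(scope="session")
def capped_matrix(small_matrix):
    return cap_vectors_per_patient(small_matrix, cap=30, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
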