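import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import connectomdmr as cdm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Two groups of 4 with fixed demographics."""
    rows = []
    for g, ages in (("A", [70, 72, 74, 76]), ("B", [71, 73, 75, 77])):
        for k, age in enumerate(ages):
            rows.append(
                {
                    "subject_id": f"{g}{k}",
                    "group": g,
                    "age": age,
                    "sex": "F" if k % 2 == 0 else "M",
                    "education_years": 16,
                }
            )
    return cdm.Cohort(pd.DataFrame(rows))


def random_sc_matrices(cohort, n_modules, rng, scale=40.0):
    """Independent Poisson SC matrices, one per cohort subject."""
    mats = []
    for sid in cohort.subject_ids:
        upper = rng.poisson(scale, size=(n_modules, n_modules))
        counts = np.triu(upper)
        counts = counts + np.triu(counts, 1).T
        mats.append(cdm.ConnectivityMatrix(subject_id=sid, counts=counts))
    return mats


@pytest.fixture
def small_matrices(small_cohort, rng):
    return random_sc_matrices(small_cohort, 6, rng)
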