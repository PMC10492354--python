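import numpy as np
import pandas as pd
import pytest

ENCOUNTER_COLUMNS = [
    "patient_id", "age_years", "sex", "specialty", "diagnosis_code",
    "diagnosis_group", "diagnosis_type", "outpatient_visits", "ed_visits",
    "inpatient_days",
]


def encounter_row(pid, specialty, *, age=70.0, sex="female", code="D001",
                  group="other circulatory disease", dtype="chronic",
                  visits=1, ed=0, days=0):
    return dict(zip(ENCOUNTER_COLUMNS,
                    [pid, age, sex, specialty, code, group, dtype,
                     visits, ed, days]))


def make_encounters(rows):
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_blob_data(rng):
    """Two well-separated 2-D point clouds of 100 points each."""
    a = rng.normal([0.0, 0.0], 0.3, size=(100, 2))
    b = rng.normal([8.0, 8.0], 0.3, size=(100, 2))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 100)
    return X, labels


def random_membership(rng, n, k):
    return rng.dirichlet(np.ones(k), size=n)
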