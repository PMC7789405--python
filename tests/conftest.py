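import numpy as np
import pandas as pd
import pytest

from cvhtraj import CohortConfig, DrugClassTable, generate_cohort


@pytest.fixture(scope="session")
def drug_table() -> DrugClassTable:
    return DrugClassTable.packaged()


@pytest.fixture(scope="session")
def small_cohort():
    """40 patients with medication orders; shared across read-only tests."""
    cfg = CohortConfig(n_patients=40, medication_probability=0.3, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def toy_measurements(rows):
    """rows: (patient_id, submetric, date, value1, value2) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "submetric", "date",
                                       "value1", "value2"])
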