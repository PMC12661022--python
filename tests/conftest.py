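import numpy as np
import pandas as pd
import pytest

import fairpul as fp


@pytest.fixture(scope="session")
def phecode_map():
    return fp.default_phecode_map()


@pytest.fixture(scope="session")
def small_config():
    return fp.default_sim_config(n_patients=4000, seed=3)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return fp.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_prepared(small_tables, phecode_map):
    return fp.prepare_cohort(small_tables, phecode_map)


@pytest.fixture(scope="session")
def small_split_result(small_prepared):
    return fp.run_split(small_prepared, seed=5, baselines=("full",))


@pytest.fixture(scope="session")
def medium_tables():
    """20k-patient default-condition cohort shared by the heavier checks."""
    return fp.generate_cohort(fp.default_sim_config(n_patients=20_000, seed=7))


@pytest.fixture(scope="session")
def medium_prepared(medium_tables, phecode_map):
    return fp.prepare_cohort(medium_tables, phecode_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_patients():
    """Hand-built patients table exercising each eligibility criterion."""
    return pd.DataFrame(
        {
            "patient_id": [f"T{i}" for i in range(7)],
            "sex": ["F", "M", "F", "F", "M", "", "F"],
            "group": ["NH-white", "HL", "EA", "NH-AfAm", "NH-white", "HL", ""],
            "age_last_visit": [70.0, 91.0, 64.9, 90.0, 65.0, 75.0, 80.0],
            "record_length": [10.0, 10.0, 10.0, 4.0, 5.0, 10.0, 10.0],
            "n_encounters": [20, 20, 20, 20, 5, 20, 20],
            "n_diagnoses": [5, 5, 5, 5, 5, 5, 5],
            "record_density": [2.0, 2.0, 2.0, 5.0, 1.0, 2.0, 2.0],
        }
    )
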