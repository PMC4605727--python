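import numpy as np
import pandas as pd
import pytest

from doserisk import (ErrorParameterSpec, SimulationConfig, parse_model_label,
                      simulate_cohort)


@pytest.fixture(scope="session")
def linear_spec():
    return parse_model_label("aD")


@pytest.fixture(scope="session")
def toy_cohort():
    """Deterministic 10-subject cohort with both genders, 2 oblasts, 3 cases."""
    return pd.DataFrame({
        "subject_id": np.arange(1, 11),
        "gender": ["male", "female"] * 5,
        "oblast": ["gomel"] * 5 + ["minsk"] * 5,
        "age_at_exposure": np.linspace(0.5, 17.5, 10),
        "age_at_screening": np.linspace(0.5, 17.5, 10) + 14.0,
        "is_case": [1, 0, 0, 1, 0, 0, 0, 1, 0, 0],
    })


@pytest.fixture(scope="session")
def toy_doses():
    return np.array([0.1, 0.5, 1.2, 3.0, 0.05, 0.8, 2.5, 4.0, 0.3, 1.0])


@pytest.fixture(scope="session")
def sim_small():
    """Moderate simulated cohort shared across read-only tests."""
    cfg = SimulationConfig(n_subjects=2000, n_realizations=20, seed=7,
                           target_cases=60)
    return simulate_cohort(cfg)


@pytest.fixture()
def zero_error_specs():
    return [ErrorParameterSpec("identity", "fixed", params={"value": 1.0})]
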