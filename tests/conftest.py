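import numpy as np
import pandas as pd
import pytest

import basalq as bq


@pytest.fixture(scope="session")
def reference_cases():
    return bq.load_reference_cases()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial synthetic cohort (fast to regenerate)."""
    return bq.generate_cohort(bq.SimParams(n_patients=10, visits_per_patient=12, seed=7))


@pytest.fixture()
def clinic_visits():
    """The three worked example visits of one patient, as a visit table."""
    return pd.DataFrame(
        {
            "patient_id": [1, 1, 1],
            "visit": [1, 2, 3],
            "hba1c": [8.1, 9.1, 8.0],
            "body_mass_index": [21.4, 24.0, 22.0],
            "activity_level": [1, 1, 1],
            "alcohol_usage": [1, 1, 1],
            "lantus_dose": [20, 22, 21],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
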