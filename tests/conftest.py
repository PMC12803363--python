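import numpy as np
import pandas as pd
import pytest

from trajimpute.simulate import SimulationConfig, simulate_cohort, cohort_tables
from trajimpute.preprocess import run_preprocess


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(n_patients=60, followup_days=1620, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return cohort_tables(small_cohort)


@pytest.fixture(scope="session")
def small_aligned(small_tables):
    aligned, medians = run_preprocess(
        small_tables["measurements"], small_tables["treatment"]
    )
    return aligned


def make_covariates(patient_ids, seed=0):
    """Simple covariate table for unit tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": list(patient_ids),
            "age_at_dx": rng.uniform(25, 80, len(patient_ids)).round(1),
            "bmi": rng.uniform(18, 40, len(patient_ids)).round(1),
            "sex": rng.choice(["F", "M"], len(patient_ids)),
            "first_line_treatment": rng.choice(
                ["imatinib", "dasatinib", "nilotinib"], len(patient_ids)
            ),
        }
    )


@pytest.fixture
def covariates_factory():
    return make_covariates
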