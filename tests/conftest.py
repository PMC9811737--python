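import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from petsig.containers import CohortTable
from petsig.simulate import default_cohort_config, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the study-condition cohort (493 x 122, calibrated
    censoring); shared across tests that only read it."""
    return simulate_cohort(default_cohort_config(seed=11))


@pytest.fixture()
def tiny_cohort():
    """Hand-written 6-patient cohort with one informative binary feature."""
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 0, 0],
            "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        }
    )
    return CohortTable(data=df, gene_cols=("x",))


def make_cohort(times, events, **features) -> CohortTable:
    """Ad-hoc cohort builder for closed-form survival checks."""
    n = len(times)
    df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                       "time_months": times, "event": events})
    for name, vals in features.items():
        df[name] = vals
    return CohortTable(data=df, gene_cols=tuple(features))
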