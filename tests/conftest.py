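import numpy as np
import pandas as pd
import pytest

from claimsagree.synth import CohortConfig, generate_cohort, sample_survey


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared across tests (read-only)."""
    return generate_cohort(CohortConfig(n_cohort=8000), seed=42)


@pytest.fixture(scope="session")
def small_survey(small_cohort):
    return sample_survey(small_cohort, per_stratum_target=200, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_events(rows):
    """Event table from (person_id, iso_date, kind, code, system) tuples."""
    df = pd.DataFrame(
        rows, columns=["person_id", "date", "kind", "code", "code_system"]
    )
    df["date"] = pd.to_datetime(df["date"])
    return df
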