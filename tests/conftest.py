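import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_tables():
    from peachferm import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture()
def small_counts_table():
    """2 stages x 2 replicates, 3 taxa, counts mode."""
    from peachferm import AbundanceTable

    data = pd.DataFrame(
        [[10, 0, 30], [8, 1, 31], [5, 5, 10], [6, 4, 10]],
        index=["A1", "A2", "B1", "B2"],
        columns=["tax_a", "tax_b", "tax_c"],
    )
    stage = pd.Series(["A", "A", "B", "B"], index=data.index)
    rep = pd.Series([1, 2, 1, 2], index=data.index)
    return AbundanceTable(data, stage, rep, mode="counts")


@pytest.fixture(scope="session")
def screening_dataset():
    from peachferm import make_screening_dataset

    return make_screening_dataset(seed=1)
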