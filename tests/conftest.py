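import numpy as np
import pandas as pd
import pytest

from tubulomics.synthetic_cohort import (
    CohortConfig,
    PRMPlan,
    generate_cohort,
    generate_prm_fixture,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One perfused-tubule cohort at the default configuration."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def prm_fixture():
    """Default planted PRM transition table: 6 clean, 2 ppm, 1 window,
    1 coelution outlier across 2 peptides."""
    return generate_prm_fixture(plan=PRMPlan(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_matrix():
    """Complete positive 3x4 intensity matrix with distinct values."""
    return pd.DataFrame(
        [[2.0, 5.0, 11.0, 17.0], [3.0, 7.0, 13.0, 19.0], [4.5, 9.0, 16.0, 23.0]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )
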