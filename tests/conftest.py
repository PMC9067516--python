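import numpy as np
import pandas as pd
import pytest

from gutdev import AbundanceTable, default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-sample default cohort shared across read-only tests."""
    return generate_cohort(default_config(n_samples=150, seed=42))


@pytest.fixture()
def toy_counts():
    """4 samples x 3 features with hand-checkable structure."""
    return AbundanceTable(
        pd.DataFrame(
            [[5, 0, 5], [8, 2, 0], [0, 0, 10], [3, 3, 4]],
            index=["s1", "s2", "s3", "s4"],
            columns=["fA", "fB", "fC"],
        ),
        kind="counts",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
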