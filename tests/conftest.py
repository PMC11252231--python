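import numpy as np
import pandas as pd
import pytest

import soiltrace as st


@pytest.fixture(scope="session")
def refset():
    return st.default_reference_set()


@pytest.fixture(scope="session")
def survey_stats():
    stats, n = st.load_survey_summary()
    return stats, n


@pytest.fixture(scope="session")
def emulated():
    """The fixed survey-emulation fixture used by qualitative checks."""
    return st.emulate_study(seed=0)


@pytest.fixture()
def toy_table():
    """Small hand-sized table: 5 sites, 3 elements, all positive."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=0.4, size=(5, 3)),
        index=[f"s{i}" for i in range(5)],
        columns=["Cd", "Ni", "Pb"],
    )
    return st.SampleTable(data)


def standardized_column(
    n: int, mean: float, sd: float, seed: int = 0, skewed: bool = False
) -> np.ndarray:
    """A column whose sample mean and sd (ddof=1) are exactly as requested.

    ``skewed`` draws the base sample from a lognormal, whose standardized
    values are bounded below by -1/CV — use it when sd is a large fraction
    of the mean and the column must stay positive.
    """
    rng = np.random.default_rng(seed)
    z = rng.lognormal(0.0, 1.0, n) if skewed else rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
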