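import numpy as np
import pandas as pd
import pytest

from riverch4.synthetic import SyntheticConfig, generate_study
from _helpers import make_reach_row


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic study shared across tests (50 reaches, 500 obs)."""
    return generate_study(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_reaches(small_study):
    return small_study["reaches"]




@pytest.fixture
def single_reach():
    return pd.DataFrame([make_reach_row()])


@pytest.fixture
def flat_concentrations():
    """Constant concentration field for the single reach."""
    return pd.DataFrame({"reach_id": "r0", "month": range(1, 13),
                         "c_hat": 1.0, "c_sd": 0.0})
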