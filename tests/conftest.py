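import numpy as np
import pandas as pd
import pytest

from capsim.synthetic import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=12345)


@pytest.fixture(scope="session")
def default_data(default_config):
    """(panel, population, policy, truth) for the default 8-state generator."""
    return generate_all(default_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(
        seed=12345,
        noise_sd={"patients": 0.0, "revenue_pc": 0.0, "fte_cost": 0.0, "cpi": 0.0},
    )


@pytest.fixture(scope="session")
def noiseless_data(noiseless_config):
    return generate_all(noiseless_config)


def make_shares_table(rows):
    """FederalShareTable from plain dict rows (testing helper).

    Each row needs state, year, group, enrollees, medicaid_revenue,
    match_rate; derived columns are computed as in the package.
    """
    from capsim.scenarios import FederalShareTable

    df = pd.DataFrame(rows)
    df["federal"] = df["match_rate"] * df["medicaid_revenue"]
    df["state_share"] = df["medicaid_revenue"] - df["federal"]
    df["per_capita_expenditure"] = np.where(
        df["enrollees"] > 0, df["medicaid_revenue"] / df["enrollees"], 0.0)
    return FederalShareTable(df)
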