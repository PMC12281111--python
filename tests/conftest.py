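import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from causalreport import validate_query
from causalreport.simulate import default_query, generate, make_scenario

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def toy4():
    """4-row table whose OLS solution is checkable by hand via the
    normal equations: Y on intercept + a + w."""
    return pd.DataFrame(
        {"y": [1.0, 3.0, 2.0, 5.0], "a": [0, 1, 0, 1], "w": [0.0, 0.0, 1.0, 1.0]}
    )


@pytest.fixture
def saturated_table():
    """One binary confounder, additive cell means.

    Cell means: (a=0,w=0)->1, (a=1,w=0)->3, (a=0,w=1)->2, (a=1,w=1)->4,
    so the stratum-standardization ATE is exactly 2 and an additive
    outcome model reproduces every cell mean exactly.
    """
    rows = []
    cells = {
        (0, 0): [0.5, 1.0, 1.5] * 3,
        (1, 0): [2.5, 3.5] * 3,
        (0, 1): [1.5, 2.5] * 3,
        (1, 1): [3.0, 4.0, 4.5, 4.5] * 3,
    }
    for (a, w), ys in cells.items():
        rows.extend((a, w, y) for y in ys)
    return pd.DataFrame(rows, columns=["a", "w", "y"])


def stratum_ate(df, a="a", w="w", y="y"):
    """Brute-force nonparametric standardization over strata of one
    discrete confounder: sum_w P(W=w) * (E[Y|A=1,w] - E[Y|A=0,w])."""
    total = 0.0
    for val, grp in df.groupby(w):
        diff = grp.loc[grp[a] == 1, y].mean() - grp.loc[grp[a] == 0, y].mean()
        total += (len(grp) / len(df)) * diff
    return total


@pytest.fixture(scope="session")
def linear_run():
    """A small validated linear-scenario dataset shared across tests."""
    scen = make_scenario("linear", n=600, seed=11)
    df, truth = generate(scen)
    query = default_query(scen, bootstrap_reps=60, seed=11)
    data = validate_query(query, df)
    return data, data.query, truth


@pytest.fixture(scope="session")
def big_linear_run():
    """Large well-overlapped dataset for asymptotic balance/overlap checks."""
    scen = make_scenario("linear", n=50_000, seed=3)
    df, _ = generate(scen)
    query = default_query(scen)
    data = validate_query(query, df)
    return data, data.query
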