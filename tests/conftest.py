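import numpy as np
import pandas as pd
import pytest

from fedgamlss import ModelSpec, SimConfig, simulate_growth, simulate_sbp


@pytest.fixture(scope="session")
def sbp_tables():
    """Heteroscedastic SBP-like data: two countries, one node each, n=4000."""
    cfg = SimConfig(scenario="sbp_hetero", n_per_node=[2000, 2000], seed=7)
    tables, truth = simulate_sbp(cfg)
    return tables, truth


@pytest.fixture(scope="session")
def sbp_spec():
    return ModelSpec(
        family="NO",
        formulas={"mu": "1 + sex + bmi", "sigma": "1 + country"},
        response="sbp",
    )


@pytest.fixture(scope="session")
def growth_no_tables():
    """Normal growth-curve data (age/height), n=2000 over two nodes."""
    cfg = SimConfig(scenario="growth_NO", n_per_node=[1000, 1000], seed=3)
    tables, truth = simulate_growth(cfg)
    return tables, truth


@pytest.fixture(scope="session")
def growth_no_spec():
    return ModelSpec(
        family="NO",
        formulas={"mu": "1 + age + pb(age)", "sigma": "1 + age + pb(age)"},
        response="height",
    )


@pytest.fixture(scope="session")
def growth_no_pooled(growth_no_tables):
    tables, _ = growth_no_tables
    return pd.concat(tables.values(), ignore_index=True)


def rel_err(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12))
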