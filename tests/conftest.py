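import numpy as np
import pandas as pd
import pytest

from phcqual import SyntheticConfig, default_catalog, generate_tables


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_patients=400, n_providers=150, n_charts=400, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_config, catalog):
    return generate_tables(small_config, catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_indicator_matrix(rng, n_units=8, n_items=5, missing=0.0):
    """Small ad-hoc matrix for oracle comparisons."""
    from phcqual import IndicatorMatrix

    values = rng.integers(0, 2, size=(n_units, n_items)).astype(float)
    if missing:
        values[rng.random(values.shape) < missing] = np.nan
    cols = [f"ind_{i}" for i in range(n_items)]
    mapping = {c: ("continuity", "PHC system") for c in cols}
    return IndicatorMatrix(
        unit_ids=np.arange(n_units), values=values, mask=np.isnan(values),
        columns=cols, mapping=mapping, unit_level="patient")
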