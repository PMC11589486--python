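import numpy as np
import pandas as pd
import pytest

from oleohyst import default_cultivars, generate_dataset, run_all
from oleohyst.pipeline import build_index_tables

SUITE_SEED = 0  # fixed seed for every default-suite test


@pytest.fixture(scope="session")
def suite_tables():
    tables, _ = generate_dataset(default_cultivars(), seed=SUITE_SEED)
    return tables


@pytest.fixture(scope="session")
def index_table(suite_tables):
    return build_index_tables(suite_tables)


@pytest.fixture(scope="session")
def suite_result():
    """Full pipeline output on the default six-cultivar suite."""
    return run_all(seed=SUITE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
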