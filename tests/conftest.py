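import numpy as np
import pytest

from cisevol.coevol import ConditionalLikelihoodTable
from cisevol.phylo import PhyloModel, encode_columns
from cisevol.simulate import null_column_pool


@pytest.fixture(scope="session")
def model() -> PhyloModel:
    return PhyloModel.default()


@pytest.fixture(scope="session")
def null_pool(model):
    """Pool of independently evolved single columns shared across tests."""
    return null_column_pool(model, 8000, seed=424242)


@pytest.fixture(scope="session")
def pool_tables(model, null_pool):
    """Factory: conditional tables for random draws from the null pool."""
    cols = null_pool.columns[:, 0, :]
    codes = encode_columns(cols)
    cll = model.column_log_table()

    def make(n_instances: int, rng: np.random.Generator):
        idx = rng.integers(0, cols.shape[0], size=n_instances)
        return ConditionalLikelihoodTable(log_values=cll[codes[idx]], columns=cols[idx])

    return make
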