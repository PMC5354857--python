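import numpy as np
import pandas as pd
import pytest

from lncnet.datatypes import ExpressionMatrix
from lncnet.simulate import SimulationConfig, simulate_expression


def small_config(seed: int = 1, **kw) -> SimulationConfig:
    """A desk-scale study: 11 vs 5 samples, 100+100 genes, 20 DE genes."""
    defaults = dict(
        seed=seed,
        n_mrna=100,
        n_lncrna=100,
        n_de_up_mrna=5,
        n_de_down_mrna=5,
        n_de_up_lncrna=5,
        n_de_down_lncrna=5,
        pathway_specs=(),
        pathway_shared_de=(),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def config():
    return small_config()


@pytest.fixture
def matrix_truth(config):
    return simulate_expression(config)


def toy_matrix(values, biotypes, groups, gene_ids=None, sample_ids=None):
    """Hand-built ExpressionMatrix from a nested list."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        biotype=pd.Series(biotypes, index=gene_ids),
        groups=pd.Series(groups, index=sample_ids),
    )
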