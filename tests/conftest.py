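import numpy as np
import pytest

from seqstop import ExpressionBatch, default_gaga_hyper, default_nn_hyper


@pytest.fixture(scope="session")
def nn_hyper():
    return default_nn_hyper()


@pytest.fixture(scope="session")
def gaga_hyper():
    return default_gaga_hyper()


def make_batch(values, groups, batch_index=None, gene_ids=None) -> ExpressionBatch:
    """Assemble a small ExpressionBatch from plain arrays."""
    values = np.atleast_2d(np.asarray(values, float))
    groups = np.asarray(groups, int)
    if batch_index is None:
        batch_index = np.ones(values.shape[1], int)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionBatch(
        values=values, groups=groups, batch_index=np.asarray(batch_index, int),
        gene_ids=np.asarray(gene_ids),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
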