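import numpy as np
import pytest
import scipy.sparse as sp

from discde import CountMatrix, NormalizedMatrix, reset_features


@pytest.fixture(autouse=True)
def _clean_feature_registry():
    """Custom features registered in one test never leak into another."""
    reset_features()
    yield
    reset_features()


def make_count_matrix(dense, individuals=None, gene_ids=None, cell_ids=None):
    """CountMatrix from a dense array; individuals as one label per cell."""
    dense = np.asarray(dense)
    m, c = dense.shape
    return CountMatrix(
        sp.csr_matrix(dense),
        gene_ids if gene_ids is not None else [f"g{i}" for i in range(m)],
        cell_ids if cell_ids is not None else [f"c{j}" for j in range(c)],
        individuals,
    )


def make_normalized(dense, individuals, gene_ids=None):
    """NormalizedMatrix straight from dense values (unit testing helper)."""
    dense = np.asarray(dense, dtype=float)
    m, c = dense.shape
    return NormalizedMatrix(
        sp.csr_matrix(dense),
        gene_ids if gene_ids is not None else [f"g{i}" for i in range(m)],
        [f"c{j}" for j in range(c)],
        individuals,
    )


@pytest.fixture
def two_group_matrix():
    """6 genes × 8 cells, individuals A–D with 2 cells each."""
    rng = np.random.default_rng(42)
    dense = rng.poisson(3.0, size=(6, 8))
    dense[0] = [0, 1, 2, 0, 3, 1, 0, 2]  # guarantee mixed zeros
    inds = ["A", "A", "B", "B", "C", "C", "D", "D"]
    return make_count_matrix(dense, inds)
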