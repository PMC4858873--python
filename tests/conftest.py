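import numpy as np
import pandas as pd
import pytest

from scwaterfall import CountsMatrix, normalize


@pytest.fixture
def small_counts() -> CountsMatrix:
    """5 genes x 4 cells with mixed gates; every gene detected somewhere."""
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 20, size=(5, 4))
    meta = pd.DataFrame(
        {
            "gate": ["X1", "X1", "X2", "other"],
            "region": ["head"] * 4,
            "source": ["synthetic"] * 4,
        },
        index=pd.Index([f"c{i}" for i in range(4)], name="cell_id"),
    )
    return CountsMatrix(
        gene_ids=[f"g{i}" for i in range(5)],
        cell_ids=[f"c{i}" for i in range(4)],
        counts=counts,
        cell_meta=meta,
    )


@pytest.fixture
def random_normalized():
    """Factory: random all-positive counts matrix, normalized."""

    def make(n_genes=30, n_cells=12, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 200, size=(n_genes, n_cells))
        m = CountsMatrix(
            gene_ids=[f"g{i:03d}" for i in range(n_genes)],
            cell_ids=[f"c{i:03d}" for i in range(n_cells)],
            counts=counts,
        )
        return normalize(m)

    return make
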