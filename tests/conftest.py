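import numpy as np
import pytest

import spagae
from spagae import FIXTURES, MultiLevelGAE, simulate


@pytest.fixture(scope="session")
def tiny_sim():
    """Oracle-scale synthetic bundle (12 cells x 6 genes)."""
    return simulate(FIXTURES["tiny"])


@pytest.fixture(scope="session")
def easy_sim():
    """The directional-acceptance conditions (200 cells x 20 genes)."""
    return simulate(FIXTURES["easy"])


@pytest.fixture(scope="session")
def easy_model(easy_sim):
    dataset, truth, priors, lr_db = easy_sim
    return MultiLevelGAE.from_dataset(
        dataset, priors, lr_db,
        binarize_threshold=1e-8,  # synthetic priors are sparse; keep their support
        feature_seed=FIXTURES["easy"].seed,
    )


@pytest.fixture(scope="session")
def easy_results(easy_model):
    return easy_model.fit(test_fraction=0.3, seed=FIXTURES["easy"].seed)


@pytest.fixture(scope="session")
def easy_untrained(easy_model):
    return easy_model.fit(test_fraction=0.3, seed=FIXTURES["easy"].seed, epochs=0)


def make_dataset(coords, expression=None, gene_names=None, cell_types=None):
    """Small hand-built SpatialExpressionDataset for graph tests."""
    coords = np.asarray(coords, float)
    n = len(coords)
    if expression is None:
        expression = np.abs(np.sin(np.arange(n * 2, dtype=float))).reshape(n, 2)
    expression = np.asarray(expression, float)
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(expression.shape[1])]
    return spagae.SpatialExpressionDataset(
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_names=np.array(gene_names, dtype=object),
        expression=expression,
        coordinates=coords,
        cell_types=cell_types,
    )
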