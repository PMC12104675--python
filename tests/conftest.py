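import numpy as np
import pytest

from heterocell.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 400-cell, 5-type dataset with self-signaling L-R programs."""
    cfg = SimulationConfig(
        n_cells=400, n_genes=800, n_types=5, n_lr_pairs=10, seed=7
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def offdiag_dataset():
    """Types signal only to other types (identity design inverted)."""
    design = 1.0 - np.eye(5)
    cfg = SimulationConfig(
        n_cells=400,
        n_genes=800,
        n_types=5,
        n_lr_pairs=10,
        communication_design=design,
        seed=8,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def blob_graph():
    """A labeled graph with Gaussian class-mean features, H ~ 0.8."""
    from heterocell.simulate import generate_graph_with_homophily

    rng = np.random.default_rng(3)
    n, k, d = 300, 5, 16
    labels = rng.integers(0, k, n)
    means = rng.normal(0, 1, (k, d))
    X = means[labels] + rng.normal(0, 1.0, (n, d))
    return generate_graph_with_homophily(
        labels, 0.8, avg_degree=8, seed=4, features=X
    )
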