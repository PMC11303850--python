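import numpy as np
import pytest
import scipy.sparse as sp

import asap


@pytest.fixture
def tiny_counts():
    """3 genes x 4 cells, fixed integers."""
    vals = np.array(
        [[1, 0, 2, 0],
         [0, 3, 0, 1],
         [4, 0, 0, 2]]
    )
    return asap.CountMatrix(
        sp.csc_matrix(vals), [f"g{i}" for i in range(3)], [f"c{j}" for j in range(4)]
    )


@pytest.fixture
def random_counts():
    """50 genes x 20 cells, sparse Poisson draw, fixed seed."""
    rng = np.random.default_rng(42)
    vals = rng.poisson(0.8, size=(50, 20))
    return asap.CountMatrix(
        sp.csc_matrix(vals), [f"g{i}" for i in range(50)],
        [f"c{j}" for j in range(20)]
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """3 well-separated cell types, pure signal (rho = 1)."""
    cfg = asap.BenchmarkConfig(
        cell_types=["type00", "type01", "type02"],
        cells_per_type=60, depth=2000, rho=1.0, seed=11, D=240,
    )
    X, labels = asap.make_benchmark(cfg)
    return X, labels


@pytest.fixture(scope="session")
def pmf_generative():
    """Counts drawn from the Gamma-Poisson generative model itself:
    beta, theta ~ Gamma(1, 1), Y ~ Poisson(beta theta^T)."""
    rng = np.random.default_rng(123)
    D, L, K = 100, 50, 3
    beta = rng.gamma(1.0, 1.0, size=(D, K))
    theta = rng.gamma(1.0, 1.0, size=(L, K))
    lam = beta @ theta.T
    Y = rng.poisson(lam)
    return Y, lam, (D, L, K)
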