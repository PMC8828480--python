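import numpy as np
import pytest

import velofate as vf


@pytest.fixture(scope="session")
def small_field():
    """Small branching field shared by graph/kernel tests (fast)."""
    return vf.simulate_branching_field(
        n_cells=200, n_genes=15, n_branches=2, noise_sd=0.1, seed=7
    )


@pytest.fixture(scope="session")
def planted_chain_3():
    """Three-block planted chain with a small leak (irreducible)."""
    return vf.simulate_planted_chain(
        [60, 60, 60], leak=1e-3, block_topology="cycle", seed=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_row_stochastic(n, rng, density=0.2):
    """Dense random irreducible row-stochastic matrix (test helper)."""
    A = rng.uniform(size=(n, n)) * (rng.uniform(size=(n, n)) < density)
    A += np.eye(n) * 0.1                       # self mass
    A[np.arange(n), (np.arange(n) + 1) % n] += 0.1  # cycle backbone
    return A / A.sum(axis=1, keepdims=True)
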