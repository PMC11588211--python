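import numpy as np
import pytest

from sducl import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A 6x10 layered slide with 3 domains, used across I/O and feature tests."""
    return generate(
        SyntheticSpec(grid_shape=(6, 10), n_domains=3, n_genes=60,
                      n_markers_per_domain=8, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_adjacency(rng, n, p=0.2):
    """Symmetric 0/1 adjacency with zero diagonal (Erdos–Renyi)."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T
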