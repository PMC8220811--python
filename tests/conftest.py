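import numpy as np
import pytest

from drgcn import RegulationNetwork


@pytest.fixture
def chain_network() -> RegulationNetwork:
    """Three-gene chain g1 -> g2 -> g3, no self-loops."""
    adj = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.uint8)
    return RegulationNetwork(["g1", "g2", "g3"], adj)


@pytest.fixture
def triangle_network() -> RegulationNetwork:
    """Symmetric triangle with self-loops: every in- and out-degree is 3."""
    adj = np.ones((3, 3), dtype=np.uint8)
    return RegulationNetwork(["g1", "g2", "g3"], adj)


def random_digraph(rng: np.random.Generator, n_genes: int, p: float) -> RegulationNetwork:
    adj = (rng.random((n_genes, n_genes)) < p).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return RegulationNetwork([f"g{i}" for i in range(n_genes)], adj)
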