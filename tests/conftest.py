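import numpy as np
import pytest

from restconn.graph import CostGraph
from restconn.spectral import Recording


@pytest.fixture
def two_cliques() -> CostGraph:
    """Two disjoint 4-cliques: the canonical planted 2-module graph."""
    adj = np.zeros((8, 8), dtype=int)
    adj[:4, :4] = 1
    adj[4:, 4:] = 1
    np.fill_diagonal(adj, 0)
    return CostGraph(adjacency=adj, cost=1.0, n=8)


@pytest.fixture
def noise_recording() -> Recording:
    rng = np.random.default_rng(42)
    return Recording(data=rng.standard_normal((4, 5000)), fs=250.0)


def random_graph(n: int, p: float, seed: int) -> CostGraph:
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    adj = (upper | upper.T).astype(int)
    return CostGraph(adjacency=adj, cost=1.0, n=n)
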