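import numpy as np
import pytest

from bilink.network import BipartiteNetwork

TOY_EDGES = [("p1", "d1"), ("p1", "d2"), ("p2", "d1"), ("p2", "d3"), ("p3", "d2")]


@pytest.fixture
def toy_net() -> BipartiteNetwork:
    """Small worked example: 3 probiotic-like and 3 disease-like nodes, 5 edges."""
    return BipartiteNetwork(["p1", "p2", "p3"], ["d1", "d2", "d3"], TOY_EDGES)


def random_network(rng: np.random.Generator, n_a: int = 30, n_b: int = 40,
                   density: float = 0.1) -> BipartiteNetwork:
    """Erdos-Renyi-style random bipartite network for property tests."""
    a_ids = [f"a{i:03d}" for i in range(n_a)]
    b_ids = [f"b{i:03d}" for i in range(n_b)]
    mask = rng.random((n_a, n_b)) < density
    edges = [(a_ids[i], b_ids[j]) for i, j in zip(*np.nonzero(mask))]
    return BipartiteNetwork(a_ids, b_ids, edges)
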