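import itertools

import numpy as np
import pytest

from metalp.graph import Graph, Partition


def build_graph(edges, weights=None, extra_nodes=()):
    """Small-graph builder for tests: edges as (u, v) pairs."""
    g = Graph()
    for idx, (u, v) in enumerate(edges):
        g.add_edge(u, v, weights[idx] if weights else 1.0)
    for u in extra_nodes:
        g.add_node(u)
    return g


def random_graph_and_partition(rng, max_n=20, dyadic_weights=False):
    """Random graph plus random partition, for property checks.

    With dyadic_weights=True every weight is a multiple of 1/8, so sums
    are exact in binary floating point regardless of accumulation order.
    """
    n = int(rng.integers(2, max_n + 1))
    g = Graph()
    for u in range(n):
        g.add_node(u)
    p_edge = min(1.0, rng.uniform(0.1, 0.6))
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < p_edge:
            if dyadic_weights:
                w = int(rng.integers(1, 65)) / 8.0
            else:
                w = float(rng.uniform(0.1, 5.0))
            g.add_edge(u, v, w)
    k = int(rng.integers(1, n + 1))
    membership = {u: int(rng.integers(k)) for u in range(n)}
    return g, Partition(membership)


@pytest.fixture(scope="session")
def karate():
    from metalp.datasets import karate_club

    return karate_club()


@pytest.fixture(scope="session")
def karate_truth():
    from metalp.datasets import karate_factions

    return karate_factions()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
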