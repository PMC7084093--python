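import itertools

import numpy as np
import pytest

from triaudit import UndirectedGraph


def brute_force_triangles(graph: UndirectedGraph) -> int:
    """Exhaustive O(n^3) triangle enumeration — independent oracle."""
    adj = graph.adjacency_sets()
    count = 0
    for i, j, k in itertools.combinations(range(graph.n), 3):
        if j in adj[i] and k in adj[i] and k in adj[j]:
            count += 1
    return count


def random_graph(n: int, p: float, seed: int) -> UndirectedGraph:
    """Seeded Erdős–Rényi G(n, p)."""
    rng = np.random.default_rng(seed)
    edges = set()
    for i in range(n - 1):
        hits = np.nonzero(rng.random(n - i - 1) < p)[0]
        edges.update((i, int(i + 1 + j)) for j in hits)
    return UndirectedGraph(n=n, edges=edges)


def complete_graph(n: int) -> UndirectedGraph:
    return UndirectedGraph(
        n=n, edges={(i, j) for i in range(n) for j in range(i + 1, n)}
    )


@pytest.fixture
def k3():
    return complete_graph(3)


@pytest.fixture
def k4():
    return complete_graph(4)
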