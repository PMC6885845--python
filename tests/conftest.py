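"""Shared fixtures and the exhaustive modularity oracle.

The oracle enumerates every set partition of a small vertex set
(restricted-growth strings, Bell(7) = 877 at most) and scores each with
the pairwise modularity definition, giving a ground-truth maximum
independent of the swarm optimizer.
"""

import numpy as np
import pytest

from udpso import WeightedGraph, modularity


def all_partitions(n):
    """Yield every set partition of {0..n-1} as a canonical label vector."""
    labels = np.zeros(n, dtype=int)

    def rec(i, n_used):
        if i == n:
            yield labels.copy()
            return
        for c in range(n_used + 1):
            labels[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(1, 1) if n > 1 else iter([labels.copy()])


def brute_force_max_modularity(graph):
    """Exhaustive maximum modularity over all set partitions."""
    best_q = -np.inf
    best_labels = None
    for labels in all_partitions(graph.n):
        q = modularity(graph, labels)
        if q > best_q:
            best_q = q
            best_labels = labels
    return best_q, best_labels


def random_weighted_graph(seed, n, density_threshold=0.3):
    """Seeded random symmetric weighted graph with some sparsity."""
    rng = np.random.default_rng(seed)
    while True:
        a = rng.random((n, n))
        a = (a + a.T) / 2.0
        a[a < density_threshold] = 0.0
        np.fill_diagonal(a, 0.0)
        if a.sum() > 0:
            return WeightedGraph(a)


@pytest.fixture
def two_edge_graph():
    """Two disjoint unit-weight edges {0-1}, {2-3}."""
    a = np.zeros((4, 4))
    a[0, 1] = a[1, 0] = 1.0
    a[2, 3] = a[3, 2] = 1.0
    return WeightedGraph(a)


@pytest.fixture
def four_cycle():
    """Unit-weight 4-cycle 0-1-2-3-0."""
    a = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        a[i, j] = a[j, i] = 1.0
    return WeightedGraph(a)


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles on 6 vertices."""
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return WeightedGraph(a)
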