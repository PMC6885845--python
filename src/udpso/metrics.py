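"""Partition-quality metrics: modularity, conductance, NMI.

Modularity Q of a weighted partitioned graph is the fraction of edge
weight falling within communities minus its expectation under the
degree-preserving random null model,

    Q = (1/2m) * sum_ij [a_ij - k_i k_j / (2m)] * delta(c_i, c_j),

summed over all ordered vertex pairs.  Conductance of a cluster C is the
cut weight leaving C over the smaller of the volumes of C and its
complement; the partition score is the average over nonempty clusters.
Higher Q is better; lower conductance is better.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .graph_io import Partition, WeightedGraph

__all__ = [
    "modularity",
    "modularity_matrix",
    "modularity_trace",
    "conductance",
    "nmi",
]


def _as_labels(partition, n: int) -> np.ndarray:
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition, int)
    if labels.size != n:
        raise ValueError(f"partition has {labels.size} labels for a {n}-vertex graph")
    return labels


def _require_edges(graph: WeightedGraph) -> float:
    if graph.total_weight <= 0:
        raise ValueError("empty graph: total edge weight is zero")
    return 2.0 * graph.total_weight


def modularity(graph: WeightedGraph, partition) -> float:
    """Newman weighted modularity, pairwise form over all ordered pairs."""
    two_m = _require_edges(graph)
    labels = _as_labels(partition, graph.n)
    same = labels[:, None] == labels[None, :]
    k = graph.degrees
    b = graph.adjacency - np.outer(k, k) / two_m
    return float(b[same].sum() / two_m)


def modularity_matrix(graph: WeightedGraph) -> np.ndarray:
    """Modularity matrix B with B_ij = a_ij - k_i k_j / (2m); rows sum to 0."""
    two_m = _require_edges(graph)
    k = graph.degrees
    return graph.adjacency - np.outer(k, k) / two_m


def modularity_trace(graph: WeightedGraph, partition) -> float:
    """Matrix form (1/2m) Trace(X^T B X) with one-hot assignment matrix X."""
    two_m = _require_edges(graph)
    labels = _as_labels(partition, graph.n)
    n_comm = int(labels.max()) + 1 if labels.size else 1
    x = np.zeros((graph.n, n_comm))
    x[np.arange(graph.n), labels] = 1.0
    b = modularity_matrix(graph)
    return float(np.trace(x.T @ b @ x) / two_m)


def conductance(graph: WeightedGraph, partition) -> float:
    """Mean cluster conductance phi(C) = cut(C) / min(vol(C), vol(~C)).

    Averaged over nonempty clusters; zero-volume clusters contribute 0,
    and a single-cluster partition scores 0 by convention (its complement
    is empty, a 0/0 cut).
    """
    _require_edges(graph)
    labels = _as_labels(partition, graph.n)
    k = graph.degrees
    total_vol = k.sum()
    communities = np.unique(labels)
    if communities.size == 1:
        return 0.0
    phis = []
    for c in communities:
        mask = labels == c
        vol = k[mask].sum()
        denom = min(vol, total_vol - vol)
        if denom <= 0:
            phis.append(0.0)
            continue
        cut = graph.adjacency[np.ix_(mask, ~mask)].sum()
        phis.append(cut / denom)
    return float(np.mean(phis))


def nmi(p, q) -> float:
    """Normalized mutual information between two partitions, in [0, 1]."""
    p_labels = p.labels if isinstance(p, Partition) else np.asarray(p, int)
    q_labels = q.labels if isinstance(q, Partition) else np.asarray(q, int)
    if p_labels.size != q_labels.size:
        raise ValueError("partitions have different lengths")
    return float(normalized_mutual_info_score(p_labels, q_labels))
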