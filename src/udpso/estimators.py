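"""Scikit-learn style estimators for swarm community detection.

``UPSOCommunityDetection`` is a clusterer over a precomputed weighted
adjacency matrix (like ``SpectralClustering(affinity="precomputed")``):
``fit(X)`` expects a square symmetric nonnegative matrix and exposes the
detected community labels as ``labels_``.  Setting
``uniform_design=False`` yields the plain-PSO ablation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .graph_io import WeightedGraph
from .swarm import UPSOConfig, _run_sweep

__all__ = ["UPSOCommunityDetection", "PSOCommunityDetection"]


class UPSOCommunityDetection(ClusterMixin, BaseEstimator):
    """Community detection by particle swarm optimization with uniform
    experimental design.

    Maximizes weighted modularity over partitions of a graph given as a
    precomputed adjacency matrix, sweeping the community count K from
    ``k_min`` to ``k_max`` and keeping the best-Q partition.

    Parameters
    ----------
    n_pop : int, default=100
        Swarm size.
    t_max : int, default=100
        Maximum iterations per fixed-K run.
    w_min, w_max : float
        Linearly decreasing inertia-weight range.
    c1, c2, c3 : float, default=2.0
        Acceleration coefficients toward the personal best, global best,
        and regulated-centroid attractors.
    s_subspaces : int, default=4
        Power-of-two subspace count for uniform-design initialization.
    q0 : int, default=31
        Uniform-design points per subspace (prime; s_subspaces*q0 >= n_pop).
    q1 : int, default=5
        Offspring per crossover parent pair (prime).
    k_min, k_max : int
        Community-count sweep range; ``k_max=None`` means min(N, 20).
    stall_fraction : float, default=0.3
        Terminate a fixed-K run when the global best is unchanged for
        ``ceil(stall_fraction * t_max)`` consecutive iterations.
    uniform_design : bool, default=True
        Disable for the plain-PSO ablation (random initialization, no
        crossover).
    random_state : int or None
        Seed for all stochastic components.

    Attributes
    ----------
    labels_ : ndarray of shape (n_vertices,)
        Community label of each vertex.
    modularity_ : float
        Modularity Q of the returned partition.
    conductance_ : float
        Mean cluster conductance of the returned partition.
    n_communities_ : int
        Effective (nonempty) community count of the winner.
    per_k_history_ : dict
        Best Q found at each swept K.
    trace_ : ndarray
        Global-best Q after initialization and after each iteration of
        the winning fixed-K run.
    termination_ : str
        "t_max" or "stall".
    """

    def __init__(
        self,
        n_pop: int = 100,
        t_max: int = 100,
        w_min: float = 0.1,
        w_max: float = 1.0,
        c1: float = 2.0,
        c2: float = 2.0,
        c3: float = 2.0,
        s_subspaces: int = 4,
        q0: int = 31,
        q1: int = 5,
        k_min: int = 1,
        k_max: int | None = None,
        stall_fraction: float = 0.3,
        uniform_design: bool = True,
        random_state: int | None = None,
    ):
        self.n_pop = n_pop
        self.t_max = t_max
        self.w_min = w_min
        self.w_max = w_max
        self.c1 = c1
        self.c2 = c2
        self.c3 = c3
        self.s_subspaces = s_subspaces
        self.q0 = q0
        self.q1 = q1
        self.k_min = k_min
        self.k_max = k_max
        self.stall_fraction = stall_fraction
        self.uniform_design = uniform_design
        self.random_state = random_state

    def _config(self) -> UPSOConfig:
        return UPSOConfig(
            n_pop=self.n_pop,
            t_max=self.t_max,
            w_min=self.w_min,
            w_max=self.w_max,
            c1=self.c1,
            c2=self.c2,
            c3=self.c3,
            s_subspaces=self.s_subspaces,
            q0=self.q0,
            q1=self.q1,
            k_min=self.k_min,
            k_max=self.k_max,
            stall_fraction=self.stall_fraction,
            seed=self.random_state,
        )

    @staticmethod
    def _as_graph(X) -> WeightedGraph:
        if isinstance(X, WeightedGraph):
            return X
        a = np.asarray(X, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"X must be a square adjacency matrix, got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("X contains non-finite entries")
        if np.any(a < 0):
            raise ValueError("X has negative entries; preprocess first")
        if np.max(np.abs(a - a.T), initial=0.0) > 1e-9:
            raise ValueError("X must be symmetric to within 1e-9")
        a = (a + a.T) / 2.0
        a = a.copy()
        np.fill_diagonal(a, 0.0)  # self-loops carry no community information
        return WeightedGraph(a)

    def fit(self, X, y=None):
        """Detect communities on the adjacency matrix ``X``."""
        graph = self._as_graph(X)
        result = _run_sweep(graph, self._config(), uniform_design=self.uniform_design)
        self.labels_ = result.best_partition.labels
        self.modularity_ = result.best_q
        self.conductance_ = result.best_conductance
        self.n_communities_ = result.chosen_k
        self.per_k_history_ = result.per_k_history
        self.trace_ = result.gbest_trace
        self.termination_ = result.termination
        self.result_ = result
        return self


class PSOCommunityDetection(UPSOCommunityDetection):
    """Plain-PSO ablation: the same optimizer with uniform-design
    initialization and crossover removed."""

    def __init__(
        self,
        n_pop: int = 100,
        t_max: int = 100,
        w_min: float = 0.1,
        w_max: float = 1.0,
        c1: float = 2.0,
        c2: float = 2.0,
        c3: float = 2.0,
        s_subspaces: int = 4,
        q0: int = 31,
        q1: int = 5,
        k_min: int = 1,
        k_max: int | None = None,
        stall_fraction: float = 0.3,
        random_state: int | None = None,
    ):
        super().__init__(
            n_pop=n_pop,
            t_max=t_max,
            w_min=w_min,
            w_max=w_max,
            c1=c1,
            c2=c2,
            c3=c3,
            s_subspaces=s_subspaces,
            q0=q0,
            q1=q1,
            k_min=k_min,
            k_max=k_max,
            stall_fraction=stall_fraction,
            uniform_design=False,
            random_state=random_state,
        )
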