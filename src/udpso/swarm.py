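"""Particle-swarm community detection with uniform-design hybridization.

A candidate solution for K communities on an N-vertex weighted graph is
the concatenation of K community centroids, each a length-N vector in
[0, 1]^N, giving a K*N-dimensional particle position.  Decoding assigns
every vertex to the community whose centroid is closest (Euclidean
distance between the vertex's adjacency row and the centroid); the
particle's fitness is the modularity Q of the decoded partition.

The full algorithm ("UPSO") augments a canonical inertia-weight PSO
with three uniform-design ingredients and a centroid regulation step:

* initialization samples S*Q0 good-lattice-point candidates over a
  bisected [0,1]^{K*N} box and keeps the best N_pop;
* each particle is regulated by recomputing the centroids of its decoded
  communities (the mean adjacency row of the members) and accepting the
  recomputed position when it strictly improves fitness;
* velocities follow a three-attractor rule pulled toward the personal
  best, the global best, and the regulated-centroid position;
* a quantized uniform-design crossover of each particle with its personal
  best and with the global best proposes 2*Q1 offspring per particle per
  iteration, accepted on strict improvement.

The uniform-design-free ablation ("PSO") replaces the initialization by
uniform random sampling and skips the crossover step entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .graph_io import Partition, WeightedGraph
from .metrics import conductance as _conductance
from .metrics import modularity as _modularity
from .uniform_design import SIGMA_TABLE, ud_candidates, ud_crossover

__all__ = [
    "UPSOConfig",
    "FixedKResult",
    "CommunityResult",
    "decode_position",
    "fitness",
    "centroid_update",
    "regulate",
    "inertia_weight",
    "update_velocity_position",
    "crossover_step",
    "run_upso_fixed_k",
    "run_upso",
    "run_pso",
]

#: Fitness improvements at or below this are treated as "unchanged" by the
#: stall-based terminal condition.
STALL_EPS = 1e-12


@dataclass
class UPSOConfig:
    """Tunable parameters of the swarm optimizer.

    Defaults are the reference operating point for 264-ROI connectomes:
    N_pop=100 particles, t_max=100 iterations, linearly decreasing inertia
    from w_max=1.0 to w_min=0.1, acceleration coefficients c1=c2=c3=2,
    S=4 subspaces of Q0=31 uniform-design points each (S*Q0=124 >= N_pop),
    Q1=5 crossover offspring per parent pair, and termination on t > t_max
    or on a global best unchanged for >= 30% of t_max iterations.
    """

    n_pop: int = 100
    t_max: int = 100
    w_min: float = 0.1
    w_max: float = 1.0
    c1: float = 2.0
    c2: float = 2.0
    c3: float = 2.0
    s_subspaces: int = 4
    q0: int = 31
    q1: int = 5
    k_min: int = 1
    k_max: int | None = None  # defaults to min(N, 20) at run time
    stall_fraction: float = 0.3
    seed: int | None = None
    vector_r: bool = False  # draw r1,r2,r3 per dimension instead of per particle

    def validate(self) -> None:
        if self.n_pop < 1:
            raise ValueError("n_pop must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not 0 <= self.w_min <= self.w_max:
            raise ValueError("need 0 <= w_min <= w_max")
        if self.s_subspaces < 1 or (self.s_subspaces & (self.s_subspaces - 1)) != 0:
            raise ValueError("S must be a power of two")
        if self.q0 not in SIGMA_TABLE or self.q1 not in SIGMA_TABLE:
            raise ValueError(f"Q0 and Q1 must be primes in {sorted(SIGMA_TABLE)}")
        if self.s_subspaces * self.q0 < self.n_pop:
            raise ValueError("S*Q0 must be >= n_pop")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if not 0 < self.stall_fraction <= 1:
            raise ValueError("stall_fraction must be in (0, 1]")


@dataclass
class FixedKResult:
    """Outcome of one fixed-K swarm run."""

    best_q: float
    partition: Partition
    trace: np.ndarray  # gbest fitness after init and after each iteration
    n_iterations: int
    termination: str  # "t_max" or "stall"


@dataclass
class CommunityResult:
    """Outcome of the full K-sweep."""

    best_partition: Partition
    best_q: float
    best_conductance: float
    chosen_k: int  # effective (nonempty) community count of the winner
    per_k_history: dict[int, float]
    gbest_trace: np.ndarray
    termination: str
    seed: int | None
    method: str = "upso"


# ---------------------------------------------------------------------------
# elementary operations


def decode_position(position, graph: WeightedGraph, k: int) -> Partition:
    """Assign each vertex to its nearest centroid (ties -> lowest index)."""
    position = np.asarray(position, dtype=float)
    n = graph.n
    if position.size != k * n:
        raise ValueError(f"position length {position.size} != K*N = {k * n}")
    centroids = position.reshape(k, n)
    a = graph.adjacency
    # squared distances via expansion; row norms cancel in the argmin
    d2 = (centroids**2).sum(axis=1)[None, :] - 2.0 * (a @ centroids.T)
    labels = np.argmin(d2, axis=1)
    return Partition(labels, k)


def fitness(position, graph: WeightedGraph, k: int) -> tuple[float, Partition]:
    """Modularity of the decoded partition, returned with the partition."""
    part = decode_position(position, graph, k)
    return _modularity(graph, part), part


def _batch_fitness(positions: np.ndarray, graph: WeightedGraph, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fitness of a (B, K*N) batch of positions.

    Returns ``(q_values, labels)`` with labels of shape (B, N).  Uses the
    community-aggregated form of modularity, algebraically identical to
    the ordered-pair sum.
    """
    b = positions.shape[0]
    n = graph.n
    a = graph.adjacency
    cents = positions.reshape(b * k, n)
    d2 = (cents**2).sum(axis=1)[None, :] - 2.0 * (a @ cents.T)  # (n, b*k)
    labels = np.argmin(d2.reshape(n, b, k), axis=2).T  # (b, n)
    deg = graph.degrees
    two_m = 2.0 * graph.total_weight
    qs = np.empty(b)
    for i in range(b):
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels[i]] = 1.0
        within = np.einsum("ck,cd,dk->k", onehot, a, onehot)
        vol = onehot.T @ deg
        qs[i] = (within / two_m - (vol / two_m) ** 2).sum()
    return qs, labels


def centroid_update(partition: Partition, graph: WeightedGraph, previous=None) -> np.ndarray:
    """Recompute each community centroid as the mean adjacency row of its
    members; an empty community keeps its previous centroid (zeros if no
    previous position is supplied)."""
    k = partition.k
    n = graph.n
    sums = np.zeros((k, n))
    np.add.at(sums, partition.labels, graph.adjacency)
    counts = np.bincount(partition.labels, minlength=k).astype(float)
    prev = (
        np.zeros((k, n))
        if previous is None
        else np.asarray(previous, dtype=float).reshape(k, n)
    )
    nonempty = counts > 0
    out = prev.copy()
    out[nonempty] = sums[nonempty] / counts[nonempty, None]
    return out


def regulate(
    position, fit: float, partition: Partition, graph: WeightedGraph, k: int
) -> tuple[np.ndarray, float, Partition, np.ndarray]:
    """Centroid-regulation step.

    Builds the candidate position KC from the recomputed community
    centroids and accepts it only on strict fitness improvement.  Returns
    ``(position, fitness, partition, kc)``; KC is returned regardless of
    acceptance because it also serves as the third velocity attractor.
    """
    kc = centroid_update(partition, graph, previous=position).ravel()
    kc_fit, kc_part = fitness(kc, graph, k)
    if kc_fit > fit:
        return kc.copy(), kc_fit, kc_part, kc
    return np.asarray(position, dtype=float), fit, partition, kc


def inertia_weight(t: int, t_max: int, w_min: float, w_max: float) -> float:
    """Linearly decreasing inertia: w = w_max - t*(w_max - w_min)/t_max."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return w_max - t * (w_max - w_min) / t_max


def update_velocity_position(
    x, s, pbest, gbest, kc, w, c1, c2, c3, rng, vector_r: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Three-attractor velocity update followed by the position step.

    s' = w*s + c1*r1*(pbest-x) + c2*r2*(gbest-x) + c3*r3*(kc-x), with
    r1,r2,r3 fresh uniform(0,1) scalars (or per-dimension vectors when
    ``vector_r``); the velocity is clamped to [-1, 1] and the new position
    x + s' to [0, 1] componentwise.
    """
    x = np.asarray(x, dtype=float)
    for other in (s, pbest, gbest, kc):
        if np.asarray(other).shape != x.shape:
            raise ValueError("all vectors must share the particle dimension")
    shape = x.shape if vector_r else ()
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    r3 = rng.random(shape)
    s_new = (
        w * np.asarray(s)
        + c1 * r1 * (np.asarray(pbest) - x)
        + c2 * r2 * (np.asarray(gbest) - x)
        + c3 * r3 * (np.asarray(kc) - x)
    )
    np.clip(s_new, -1.0, 1.0, out=s_new)
    x_new = np.clip(x + s_new, 0.0, 1.0)
    return x_new, s_new


# ---------------------------------------------------------------------------
# swarm state and the fixed-K loop


@dataclass
class _Swarm:
    x: np.ndarray  # (npop, d) positions
    s: np.ndarray  # (npop, d) velocities
    fit: np.ndarray  # (npop,)
    labels: np.ndarray  # (npop, n) decoded affiliations
    kc: np.ndarray  # (npop, d) regulated-centroid attractors
    pbest: np.ndarray
    pbest_fit: np.ndarray
    gbest: np.ndarray = field(init=False)
    gbest_fit: float = field(init=False)
    gbest_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        g = int(np.argmax(self.pbest_fit))
        self.gbest = self.pbest[g].copy()
        self.gbest_fit = float(self.pbest_fit[g])
        self.gbest_labels = self.labels[g].copy()


def _regulate_all(swarm: _Swarm, graph: WeightedGraph, k: int) -> None:
    kc = np.empty_like(swarm.x)
    for i in range(swarm.x.shape[0]):
        part = Partition(swarm.labels[i], k)
        kc[i] = centroid_update(part, graph, previous=swarm.x[i]).ravel()
    kc_fit, kc_labels = _batch_fitness(kc, graph, k)
    better = kc_fit > swarm.fit
    swarm.x[better] = kc[better]
    swarm.fit[better] = kc_fit[better]
    swarm.labels[better] = kc_labels[better]
    swarm.kc = kc


def crossover_step(swarm: _Swarm, graph: WeightedGraph, k: int, q1: int) -> None:
    """Uniform-design crossover of every particle with its personal best
    and with the global best; strict-improvement acceptance.

    Particles are processed in order, so a global-best improvement is
    visible to subsequent particles within the same iteration.
    """
    npop = swarm.x.shape[0]
    for i in range(npop):
        offspring = np.vstack(
            [
                ud_crossover(swarm.x[i], swarm.pbest[i], q1),
                ud_crossover(swarm.x[i], swarm.gbest, q1),
            ]
        )
        off_fit, off_labels = _batch_fitness(offspring, graph, k)
        best = int(np.argmax(off_fit))
        f_ob = float(off_fit[best])
        if f_ob > swarm.pbest_fit[i]:
            swarm.x[i] = offspring[best]
            swarm.fit[i] = f_ob
            swarm.labels[i] = off_labels[best]
            swarm.pbest[i] = offspring[best]
            swarm.pbest_fit[i] = f_ob
        if f_ob > swarm.gbest_fit:
            swarm.gbest = offspring[best].copy()
            swarm.gbest_fit = f_ob
            swarm.gbest_labels = off_labels[best].copy()


def run_upso_fixed_k(
    graph: WeightedGraph,
    k: int,
    config: UPSOConfig,
    rng: np.random.Generator | None = None,
    uniform_design: bool = True,
) -> FixedKResult:
    """One swarm run at a fixed community count K.

    With ``uniform_design`` the swarm is seeded from S*Q0 good-lattice
    points and the crossover step runs every iteration; without it the
    swarm starts uniformly at random and crossover is skipped.
    """
    config.validate()
    if not 1 <= k <= graph.n:
        raise ValueError(f"K must be in 1..{graph.n}, got {k}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = graph.n
    d = k * n
    npop = config.n_pop

    if uniform_design:
        cands = ud_candidates(d, config.s_subspaces, config.q0, np.zeros(d), np.ones(d))
        cand_fit, cand_labels = _batch_fitness(cands, graph, k)
        order = np.argsort(-cand_fit, kind="stable")[:npop]
        x, fit_v, labels = cands[order], cand_fit[order], cand_labels[order]
    else:
        x = rng.random((npop, d))
        fit_v, labels = _batch_fitness(x, graph, k)

    swarm = _Swarm(
        x=x.copy(),
        s=x.copy(),  # velocities start equal to the positions
        fit=fit_v.copy(),
        labels=labels.copy(),
        kc=np.zeros_like(x),
        pbest=x.copy(),
        pbest_fit=fit_v.copy(),
    )
    _regulate_all(swarm, graph, k)
    # regulation may have improved particles before pbest/gbest bookkeeping
    improved = swarm.fit > swarm.pbest_fit
    swarm.pbest[improved] = swarm.x[improved]
    swarm.pbest_fit[improved] = swarm.fit[improved]
    g = int(np.argmax(swarm.pbest_fit))
    if swarm.pbest_fit[g] > swarm.gbest_fit:
        swarm.gbest = swarm.pbest[g].copy()
        swarm.gbest_fit = float(swarm.pbest_fit[g])
        swarm.gbest_labels = swarm.labels[g].copy()

    stall_limit = math.ceil(config.stall_fraction * config.t_max)
    trace = [swarm.gbest_fit]
    t = 0
    t_no = 0
    termination = "t_max"
    while True:
        t += 1
        if t > config.t_max:
            termination = "t_max"
            t -= 1
            break
        if t_no >= stall_limit:
            termination = "stall"
            t -= 1
            break
        w = inertia_weight(t, config.t_max, config.w_min, config.w_max)
        prev_gbest = swarm.gbest_fit

        # velocity + position (vectorized across the swarm; r scalars per particle)
        shape = (npop, d) if config.vector_r else (npop, 1)
        r1 = rng.random(shape)
        r2 = rng.random(shape)
        r3 = rng.random(shape)
        s_new = (
            w * swarm.s
            + config.c1 * r1 * (swarm.pbest - swarm.x)
            + config.c2 * r2 * (swarm.gbest[None, :] - swarm.x)
            + config.c3 * r3 * (swarm.kc - swarm.x)
        )
        np.clip(s_new, -1.0, 1.0, out=s_new)
        swarm.s = s_new
        swarm.x = np.clip(swarm.x + s_new, 0.0, 1.0)

        swarm.fit, swarm.labels = _batch_fitness(swarm.x, graph, k)
        _regulate_all(swarm, graph, k)

        improved = swarm.fit > swarm.pbest_fit
        swarm.pbest[improved] = swarm.x[improved]
        swarm.pbest_fit[improved] = swarm.fit[improved]
        g = int(np.argmax(swarm.pbest_fit))
        if swarm.pbest_fit[g] > swarm.gbest_fit:
            swarm.gbest = swarm.pbest[g].copy()
            swarm.gbest_fit = float(swarm.pbest_fit[g])
            swarm.gbest_labels = swarm.labels[g].copy()

        if uniform_design:
            crossover_step(swarm, graph, k, config.q1)

        trace.append(swarm.gbest_fit)
        if swarm.gbest_fit - prev_gbest > STALL_EPS:
            t_no = 0
        else:
            t_no += 1

    return FixedKResult(
        best_q=float(swarm.gbest_fit),
        partition=Partition(swarm.gbest_labels.copy(), k),
        trace=np.asarray(trace),
        n_iterations=t,
        termination=termination,
    )


# ---------------------------------------------------------------------------
# K sweep


def _run_sweep(graph: WeightedGraph, config: UPSOConfig, uniform_design: bool) -> CommunityResult:
    config.validate()
    k_max = config.k_max if config.k_max is not None else min(graph.n, 20)
    if k_max < config.k_min:
        raise ValueError("k_max must be >= k_min")
    if k_max > graph.n:
        raise ValueError(f"k_max exceeds the vertex count {graph.n}")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(k_max - config.k_min + 1)
    per_k: dict[int, float] = {}
    best: FixedKResult | None = None
    for k, child in zip(range(config.k_min, k_max + 1), children):
        res = run_upso_fixed_k(
            graph, k, config, rng=np.random.default_rng(child), uniform_design=uniform_design
        )
        per_k[k] = res.best_q
        if best is None or res.best_q > best.best_q:
            best = res
    assert best is not None
    # relabel the winner canonically (empty communities drop out of the ids)
    winner = Partition.from_labels(best.partition.labels)
    return CommunityResult(
        best_partition=winner,
        best_q=best.best_q,
        best_conductance=_conductance(graph, winner),
        chosen_k=winner.effective_k,
        per_k_history=per_k,
        gbest_trace=best.trace,
        termination=best.termination,
        seed=config.seed,
        method="upso" if uniform_design else "pso",
    )


def run_upso(graph: WeightedGraph, config: UPSOConfig | None = None) -> CommunityResult:
    """Sweep K = k_min..k_max with the full uniform-design swarm and
    return the best-modularity partition with its conductance."""
    return _run_sweep(graph, config or UPSOConfig(), uniform_design=True)


def run_pso(graph: WeightedGraph, config: UPSOConfig | None = None) -> CommunityResult:
    """Ablated swarm: random initialization, no uniform-design crossover."""
    return _run_sweep(graph, config or UPSOConfig(), uniform_design=False)


def config_with(config: UPSOConfig, **overrides) -> UPSOConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
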