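"""Uniform experimental design: good-lattice-point arrays, swarm
initialization, and the quantized crossover operator.

A uniform array U(n, q) selects q level combinations of n factors, each
with q levels, scattered evenly over the q^n lattice.  Its entries are
generated by the good-lattice-point rule

    U[l1, l2] = (l1 * sigma^(l2-1) mod q) + 1,   l1 = 1..q, l2 = 1..n,

where q is prime and sigma is a tabulated generator depending on (q, n).
Because q is prime, every column is a permutation of {1..q}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SIGMA_TABLE",
    "UniformArray",
    "sigma_lookup",
    "uniform_array",
    "ud_initialize",
    "ud_crossover",
]

# sigma generators for the good-lattice-point construction, keyed by the
# prime level count q; each row maps inclusive factor-count ranges to sigma.
SIGMA_TABLE: dict[int, list[tuple[tuple[tuple[int, int], ...], int]]] = {
    5: [(((2, 4),), 2)],
    7: [(((2, 6),), 3)],
    11: [(((2, 10),), 7)],
    13: [(((2, 2),), 5), (((3, 3),), 4), (((4, 12),), 6)],
    17: [(((2, 16),), 10)],
    19: [(((2, 3),), 8), (((4, 18),), 14)],
    23: [
        (((2, 2), (13, 14), (20, 22)), 7),
        (((8, 12),), 15),
        (((3, 7), (15, 19)), 17),
    ],
    29: [
        (((2, 2),), 12),
        (((3, 3),), 9),
        (((4, 7),), 16),
        (((8, 12), (16, 24)), 8),
        (((13, 15),), 14),
        (((25, 28),), 18),
    ],
    31: [(((2, 2), (5, 12), (20, 30)), 12), (((3, 4), (13, 19)), 22)],
}


@dataclass(frozen=True)
class UniformArray:
    """A q x n good-lattice-point array with 1-based levels."""

    q: int
    n: int
    sigma: int
    levels: np.ndarray  # (q, n) ints in {1..q}


def sigma_lookup(q: int, n: int) -> int:
    """Generator sigma for a U(n, q) array.

    Factor counts above the largest tabulated range for q (i.e. n > q-1)
    are clamped: level balance is preserved for any exponent because q is
    prime.
    """
    if q not in SIGMA_TABLE:
        raise ValueError(f"unsupported level count q={q}; must be one of {sorted(SIGMA_TABLE)}")
    n_eff = min(max(n, 2), q - 1)
    for ranges, sigma in SIGMA_TABLE[q]:
        if any(lo <= n_eff <= hi for lo, hi in ranges):
            return sigma
    raise AssertionError(f"sigma table has a gap at q={q}, n={n_eff}")  # pragma: no cover


def uniform_array(n: int, q: int) -> UniformArray:
    """Construct the good-lattice-point array U(n, q)."""
    if n < 1:
        raise ValueError("factor count n must be >= 1")
    sigma = sigma_lookup(q, n)
    l1 = np.arange(1, q + 1)
    # modular exponentiation keeps sigma^(l2-1) exact for any n
    powers = np.array([pow(sigma, l2, q) for l2 in range(n)], dtype=np.int64)
    levels = (l1[:, None] * powers[None, :]) % q + 1
    return UniformArray(q=q, n=n, sigma=sigma, levels=levels)


def _subspace_boxes(lower: np.ndarray, upper: np.ndarray, s: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Bisect the box into s sub-boxes along the first log2(s) coordinates.

    When the dimension is smaller than log2(s), splitting cycles through
    the coordinates, nesting the halvings.
    """
    if s < 1 or (s & (s - 1)) != 0:
        raise ValueError("subspace count S must be a power of two")
    d = lower.size
    boxes = [(lower.copy(), upper.copy())]
    n_splits = s.bit_length() - 1
    for split in range(n_splits):
        dim = split % d
        new_boxes = []
        for lo, up in boxes:
            mid = (lo[dim] + up[dim]) / 2.0
            lo_left, up_left = lo.copy(), up.copy()
            up_left[dim] = mid
            lo_right, up_right = lo.copy(), up.copy()
            lo_right[dim] = mid
            new_boxes.append((lo_left, up_left))
            new_boxes.append((lo_right, up_right))
        boxes = new_boxes
    return boxes


def ud_candidates(d: int, s: int, q0: int, lower, upper) -> np.ndarray:
    """All s*q0 uniform-design candidate points over the bisected box.

    Within each sub-box the q0 levels of U(d, q0) are mapped affinely so
    that levels 1 and q0 land on opposite faces:
    x_j = lower_j + (U - 1) / (q0 - 1) * (upper_j - lower_j).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.size != d or upper.size != d:
        raise ValueError("bounds must have length d")
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    ua = uniform_array(d, q0)
    frac = (ua.levels - 1) / (q0 - 1)  # (q0, d) in [0, 1]
    points = []
    for lo, up in _subspace_boxes(lower, upper, s):
        points.append(lo[None, :] + frac * (up - lo)[None, :])
    return np.vstack(points)


def ud_initialize(d, s, q0, npop, lower, upper, fitness) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-design swarm initialization.

    Generates s*q0 candidates with :func:`ud_candidates`, scores them all
    with ``fitness`` (a callable mapping a position vector to a scalar,
    higher better), and keeps the best ``npop``.  Fully deterministic.

    Returns ``(positions, fitnesses)`` of shape (npop, d) and (npop,).
    """
    if s * q0 < npop:
        raise ValueError(f"S*Q0 = {s * q0} must be >= the population size {npop}")
    cands = ud_candidates(d, s, q0, lower, upper)
    fits = np.array([fitness(c) for c in cands], dtype=float)
    order = np.argsort(-fits, kind="stable")[:npop]
    return cands[order], fits[order]


def ud_crossover(parent1, parent2, q1: int) -> np.ndarray:
    """Uniform-design quantized crossover: q1 offspring inside the box
    spanned by two parents.

    Each coordinate interval [min, max] is quantized into q1 ascending
    equal-step levels; offspring l1 takes level U[l1, i] of coordinate i
    from the array U(d, q1).  Deterministic; offspring are contained in
    the parents' box by construction.
    """
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("parents must be 1-d vectors of equal length")
    lo = np.minimum(p1, p2)
    hi = np.maximum(p1, p2)
    ua = uniform_array(p1.size, q1)
    frac = (ua.levels - 1) / (q1 - 1)  # (q1, d)
    return lo[None, :] + frac * (hi - lo)[None, :]
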