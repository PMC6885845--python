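"""Connectivity-matrix, edge-list and partition I/O plus preprocessing.

Resting-state fMRI connectomes are distributed as square matrices of
Fisher z-transformed Pearson correlations between regions of interest
(ROIs).  Before community detection they are mapped back to correlation
scale, negative correlations are discarded, and weak edges are removed by
thresholding, yielding a symmetric nonnegative weighted adjacency matrix
with entries in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "WeightedGraph",
    "Partition",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
    "read_edge_list",
    "write_edge_list",
    "reverse_z_transform",
    "clamp_negative",
    "threshold_edges",
    "preprocess",
    "read_partition",
    "write_partition",
]

#: Symmetry tolerance accepted on raw input (beyond this the matrix is rejected).
ASYMMETRY_TOLERANCE = 1e-6
#: Symmetry tolerance guaranteed on preprocessed graphs.
GRAPH_SYMMETRY_TOLERANCE = 1e-9


@dataclass
class ConnectivityMatrix:
    """Raw square connectivity matrix; may hold z-values and negatives."""

    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(
                f"shape error: connectivity matrix must be square, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weighted graph with zero diagonal.

    ``degrees`` holds the weighted degree k_i = sum_j a_ij and
    ``total_weight`` the total edge weight m = (sum_i k_i) / 2.
    """

    adjacency: np.ndarray
    labels: list[str] | None = None
    degrees: np.ndarray = field(init=False, repr=False)
    total_weight: float = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("adjacency contains non-finite entries")
        if np.max(np.abs(a - a.T), initial=0.0) > GRAPH_SYMMETRY_TOLERANCE:
            raise ValueError("adjacency is not symmetric")
        if np.any(a < 0):
            raise ValueError("adjacency has negative entries")
        if np.any(np.diagonal(a) != 0):
            raise ValueError("adjacency diagonal must be exactly zero")
        self.adjacency = a
        self.degrees = a.sum(axis=1)
        self.total_weight = float(self.degrees.sum()) / 2.0

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class Partition:
    """Per-vertex community labels in {0..K-1}."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in {0..K-1}")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def effective_k(self) -> int:
        """Number of nonempty communities."""
        return int(np.unique(self.labels).size)

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        """Canonicalize arbitrary integer labels to contiguous 0-based ids.

        Communities are numbered in order of first appearance.
        """
        labels = np.asarray(labels, dtype=int)
        seen: dict[int, int] = {}
        out = np.empty_like(labels)
        for i, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(seen)
            out[i] = seen[lab]
        return cls(out, max(len(seen), 1))


# ---------------------------------------------------------------------------
# matrix I/O


def _detect_delimiter(line: str) -> str | None:
    # precedence: comma, then tab, then any whitespace (None)
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None


def read_connectivity_matrix(
    path, delimiter: str | None = None, has_labels: bool | None = None
) -> ConnectivityMatrix:
    """Read a delimited square matrix, optionally with a header row and
    first label column.

    ``delimiter=None`` auto-detects (comma > tab > whitespace);
    ``has_labels=None`` auto-detects by attempting to parse the first row
    as numbers.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty file: {path}")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])
    rows = [ln.split(delimiter) if delimiter else ln.split() for ln in lines]

    if has_labels is None:
        try:
            [float(c) for c in rows[0]]
            has_labels = False
        except ValueError:
            has_labels = True

    labels: list[str] | None = None
    if has_labels:
        header = rows[0]
        body = rows[1:]
        # header may or may not carry a leading corner cell over the label column
        labels = header[1:] if len(header) == len(body[0]) else header
        rows = [r[1:] for r in body]

    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows) or len(rows) != ncols:
        raise ValueError(
            f"shape error: expected a square matrix, got {len(rows)} rows "
            f"with {ncols} columns in {path}"
        )
    values = np.empty((len(rows), ncols), dtype=float)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"parse error at row {i}, col {j}: {cell!r}"
                ) from None
    return ConnectivityMatrix(values, labels)


def write_connectivity_matrix(cm: ConnectivityMatrix | WeightedGraph, path, delimiter="\t") -> None:
    values = cm.values if isinstance(cm, ConnectivityMatrix) else cm.adjacency
    np.savetxt(path, values, delimiter=delimiter, fmt="%.12g")


def read_edge_list(path, n: int | None = None) -> WeightedGraph:
    """Read a weighted edge list (u, v, w per row, 0-based) into a graph."""
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        raise ValueError(f"empty edge list: {path}")
    if data.shape[1] != 3:
        raise ValueError("edge list rows must be: u v w")
    u = data[:, 0].astype(int)
    v = data[:, 1].astype(int)
    w = data[:, 2]
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("negative vertex id in edge list")
    size = int(max(u.max(), v.max())) + 1 if n is None else n
    a = np.zeros((size, size))
    a[u, v] = w
    a[v, u] = w
    np.fill_diagonal(a, 0.0)
    return WeightedGraph(a)


def write_edge_list(graph: WeightedGraph, path) -> None:
    iu, ju = np.triu_indices(graph.n, k=1)
    mask = graph.adjacency[iu, ju] != 0
    with open(path, "w") as fh:
        for i, j in zip(iu[mask], ju[mask]):
            fh.write(f"{i}\t{j}\t{graph.adjacency[i, j]:.12g}\n")


# ---------------------------------------------------------------------------
# preprocessing chain


def reverse_z_transform(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Map Fisher z-values back to correlations: x' = (e^{2x}-1)/(e^{2x}+1)."""
    return ConnectivityMatrix(np.tanh(cm.values), cm.labels)


def clamp_negative(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero out negative correlations."""
    return ConnectivityMatrix(np.maximum(cm.values, 0.0), cm.labels)


def threshold_edges(cm: ConnectivityMatrix, theta: float) -> ConnectivityMatrix:
    """Remove noise edges: entries strictly below ``theta`` become 0."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    values = cm.values.copy()
    values[values < theta] = 0.0
    return ConnectivityMatrix(values, cm.labels)


def preprocess(
    cm: ConnectivityMatrix, apply_reverse_z: bool = False, theta: float = 0.2
) -> WeightedGraph:
    """Full preprocessing chain producing a valid weighted graph.

    Pipeline: optional reverse z-transform -> clamp negatives -> zero the
    diagonal -> symmetrize by averaging -> threshold at ``theta``.  Raises
    on strongly asymmetric input and on an empty (zero total weight) result.
    """
    if apply_reverse_z:
        cm = reverse_z_transform(cm)
    cm = clamp_negative(cm)
    values = cm.values.copy()
    np.fill_diagonal(values, 0.0)
    asym = np.max(np.abs(values - values.T), initial=0.0)
    if asym > ASYMMETRY_TOLERANCE:
        raise ValueError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOLERANCE}"
        )
    values = (values + values.T) / 2.0
    values[values < theta] = 0.0
    if values.sum() == 0.0:
        raise ValueError("empty graph: no edges survive preprocessing")
    return WeightedGraph(values, cm.labels)


# ---------------------------------------------------------------------------
# partition I/O


def read_partition(path) -> Partition:
    """Read a two-column (vertex, community) delimited file, 0-based.

    Vertices must cover 0..N-1 exactly once.  Non-contiguous community ids
    are relabeled to a canonical contiguous form with a warning.
    """
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh):
            if not ln.strip():
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'vertex community'")
            pairs.append((int(parts[0]), int(parts[1])))
    if not pairs:
        raise ValueError(f"empty partition file: {path}")
    vertices = [v for v, _ in pairs]
    if min(vertices) < 0 or min(c for _, c in pairs) < 0:
        raise ValueError("negative id in partition file")
    if len(set(vertices)) != len(vertices):
        dup = sorted(v for v in set(vertices) if vertices.count(v) > 1)
        raise ValueError(f"duplicate vertex rows: {dup}")
    n = len(pairs)
    if set(vertices) != set(range(n)):
        missing = sorted(set(range(n)) - set(vertices))
        raise ValueError(f"missing vertex rows: {missing}")
    labels = np.empty(n, dtype=int)
    for v, c in pairs:
        labels[v] = c
    uniq = np.unique(labels)
    if not np.array_equal(uniq, np.arange(uniq.size)):
        warnings.warn(
            "community ids are not contiguous 0-based; relabeling canonically",
            stacklevel=2,
        )
        return Partition.from_labels(labels)
    return Partition(labels, int(uniq.size))


def write_partition(partition: Partition, path) -> None:
    with open(path, "w") as fh:
        for v, c in enumerate(partition.labels):
            fh.write(f"{v}\t{int(c)}\n")
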