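"""Planted-partition generator emulating correlation-type connectomes.

Produces symmetric nonnegative matrices in [0, 1] with block (community)
structure: within-block entries are drawn from a clipped Gaussian with a
high mean, between-block entries from a clipped Gaussian with a low
mean, so that thresholding at the usual theta = 0.2 removes most
between-block edges.  An optional forward Fisher z encoding lets the
full preprocessing chain be round-trip tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import ConnectivityMatrix, Partition, WeightedGraph

__all__ = ["PlantedSpec", "generate_planted_pcm", "generate_z_cm"]

# forward Fisher z of exactly 1 is infinite; entries are capped just below
Z_CLIP = 0.999


@dataclass
class PlantedSpec:
    """Parameters of a planted block correlation matrix.

    Defaults give three 12-ROI blocks with strong contrast: within-block
    weights ~ N(0.7, 0.05) and between-block weights ~ N(0.1, 0.05), both
    clipped to [0, 1], so the 0.2 threshold removes almost every
    between-block edge.
    """

    block_sizes: tuple[int, ...] = (12, 12, 12)
    w_in_mean: float = 0.7
    w_in_sd: float = 0.05
    w_out_mean: float = 0.1
    w_out_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        if sum(self.block_sizes) < 2:
            raise ValueError("total size must be >= 2")
        for m in (self.w_in_mean, self.w_out_mean):
            if not 0 <= m <= 1:
                raise ValueError("weight means must be in [0, 1]")
        if self.w_in_sd < 0 or self.w_out_sd < 0:
            raise ValueError("weight SDs must be >= 0")


def generate_planted_pcm(spec: PlantedSpec) -> tuple[WeightedGraph, Partition]:
    """Draw a planted correlation-like matrix and its ground-truth labels.

    Symmetric with zero diagonal; reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.block_sizes)
    labels = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    means = np.where(same, spec.w_in_mean, spec.w_out_mean)
    sds = np.where(same, spec.w_in_sd, spec.w_out_sd)
    vals = np.clip(rng.normal(means, sds), 0.0, 1.0)
    a = np.zeros((n, n))
    a[iu, ju] = vals
    a[ju, iu] = vals
    return WeightedGraph(a), Partition(labels, len(spec.block_sizes))


def generate_z_cm(spec: PlantedSpec) -> ConnectivityMatrix:
    """Forward Fisher z encoding of the planted matrix.

    Entries are capped at 0.999 before artanh so z-values stay finite;
    preprocessing with the reverse z-transform recovers the (capped,
    thresholded) planted matrix exactly.
    """
    graph, _ = generate_planted_pcm(spec)
    capped = np.minimum(graph.adjacency, Z_CLIP)
    return ConnectivityMatrix(np.arctanh(capped))
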