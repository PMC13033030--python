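"""Bundled monolayer state: topology, geometry, reduction, metric weights.

Most operations need several of these at once; :class:`Monolayer` computes
each lazily and caches it, so call sites can pass a single object.
"""

from __future__ import annotations

import numpy as np

from .mesh import (
    MonolayerGeometry,
    MonolayerTopology,
    MetricOperators,
    ReducedIncidence,
    build_topology,
    compute_geometry,
    euler_characteristic,
    metric_operators,
    reduce_incidence,
)

__all__ = ["Monolayer"]


class Monolayer:
    """A confluent polygonal monolayer with cached derived structure."""

    def __init__(self, cells: list[list[int]], r: np.ndarray,
                 topology: MonolayerTopology | None = None):
        self.topology = topology if topology is not None else build_topology(cells)
        self.r = np.asarray(r, dtype=float)
        self._geometry: MonolayerGeometry | None = None
        self._reduced: ReducedIncidence | None = None
        self._metric: MetricOperators | None = None

    @classmethod
    def from_topology(cls, topology: MonolayerTopology, r: np.ndarray) -> "Monolayer":
        return cls(topology.cells, r, topology=topology)

    @property
    def geometry(self) -> MonolayerGeometry:
        if self._geometry is None:
            self._geometry = compute_geometry(self.topology, self.r)
        return self._geometry

    @property
    def reduced(self) -> ReducedIncidence:
        if self._reduced is None:
            self._reduced = reduce_incidence(self.topology)
        return self._reduced

    @property
    def metric(self) -> MetricOperators:
        if self._metric is None:
            self._metric = metric_operators(self.geometry, self.reduced)
        return self._metric

    @property
    def n_vertices(self) -> int:
        return self.topology.n_vertices

    @property
    def n_edges(self) -> int:
        return self.topology.n_edges

    @property
    def n_cells(self) -> int:
        return self.topology.n_cells

    @property
    def n_holes(self) -> int:
        return self.topology.n_holes

    @property
    def euler_characteristic(self) -> int:
        return euler_characteristic(self.topology)

    def carrier_size(self, network: str, degree: int) -> int:
        """Number of carrier elements for a cochain of given degree."""
        if network == "primal":
            return (self.n_vertices, self.n_edges, self.n_cells)[degree]
        if network == "dual":
            return (self.n_cells, self.n_edges, self.n_vertices)[degree]
        raise ValueError(f"unknown network {network!r}")
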