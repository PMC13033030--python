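"""Primal/dual network construction for confluent cell monolayers.

A monolayer is a set of confluent polygonal cells.  The primal network
holds cell vertices, edges and faces; the dual network connects adjacent
cell centres by links and tiles the monolayer with the triangles spanned
by cell centres around each vertex.  Topology is encoded in two signed
incidence matrices:

* ``A`` (edges x vertices): row j has ``+1`` at the head and ``-1`` at the
  tail of edge j, so the edge vector is ``t_j = sum_k A_jk r_k``.
* ``B`` (cells x edges): ``B_ij = +1`` if cell i traverses edge j along its
  orientation, ``-1`` against it.  Closed cell boundaries give ``B A = 0``.

Cells are wound clockwise (negative shoelace signed area in right-handed
axes), the orientation represented by the fixed quarter rotation
``eps_i = [[0, -1], [1, 0]]``; triangles of the dual network carry the
opposite orientation ``eps_k = -eps_i``.  Cell areas ``A_i`` are then
positive, and link vectors are sign-fixed so that every edge-link
parallelogram area ``F_j = T_j . eps_i t_j`` is positive.

Boundary conditions are implemented by *reduced* networks: peripheral
edges and peripheral vertices (including hole boundaries created by
ablation) are suppressed by zeroing the corresponding rows/columns of A
and B, preserving ``B_hat A_hat = 0`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "EPS_I",
    "EPS_K",
    "MonolayerTopology",
    "MonolayerGeometry",
    "ReducedIncidence",
    "MetricOperators",
    "TopologyError",
    "OrientationError",
    "ConnectivityError",
    "DegenerateGeometryError",
    "build_topology",
    "euler_characteristic",
    "reduce_incidence",
    "compute_geometry",
    "metric_operators",
]

#: quarter rotation fixing the cell orientation convention; triangles carry -EPS_I
EPS_I = np.array([[0.0, -1.0], [1.0, 0.0]])
EPS_K = -EPS_I


class TopologyError(ValueError):
    """Non-manifold or otherwise invalid cell complex."""


class OrientationError(ValueError):
    """Inconsistent cell winding or negative oriented areas."""


class ConnectivityError(ValueError):
    """The cell network is not edge-connected."""


class DegenerateGeometryError(ValueError):
    """Zero-length edge, vanishing area or similar metric degeneracy."""


@dataclass
class MonolayerTopology:
    """Signed incidence description of a polygonal monolayer.

    ``A`` is (n_edges, n_vertices), ``B`` is (n_cells, n_edges), both with
    entries in {-1, 0, +1} stored as sparse integer matrices.
    """

    n_vertices: int
    n_edges: int
    n_cells: int
    A: sp.csr_matrix
    B: sp.csr_matrix
    cells: list[list[int]]
    edge_vertices: np.ndarray          # (n_edges, 2) [tail, head]
    peripheral_edges: np.ndarray       # sorted indices, edges with one cell
    peripheral_vertices: np.ndarray    # vertices incident to a peripheral edge
    n_holes: int
    hole_boundaries: list[list[int]] = field(default_factory=list)
    outer_boundary: list[int] = field(default_factory=list)

    @property
    def interior_edges(self) -> np.ndarray:
        mask = np.ones(self.n_edges, dtype=bool)
        mask[self.peripheral_edges] = False
        return np.nonzero(mask)[0]

    @property
    def interior_vertices(self) -> np.ndarray:
        mask = np.ones(self.n_vertices, dtype=bool)
        mask[self.peripheral_vertices] = False
        return np.nonzero(mask)[0]


@dataclass
class MonolayerGeometry:
    """Vertex positions plus every derived metric quantity."""

    r: np.ndarray        # (n_v, 2) vertex positions
    R: np.ndarray        # (n_c, 2) cell centres (vertex centroids)
    t: np.ndarray        # (n_e, 2) edge vectors
    T: np.ndarray        # (n_e, 2) link vectors
    c: np.ndarray        # (n_e, 2) edge centroids
    b: np.ndarray        # (n_e, 2) edge-line / link-line intersections
    A_cell: np.ndarray   # (n_c,) cell areas > 0
    E_tri: np.ndarray    # (n_v,) triangle areas around vertices
    F: np.ndarray        # (n_e,) parallelogram areas T . eps_i t
    t_len: np.ndarray
    T_len: np.ndarray
    C_adj: sp.csr_matrix  # (n_c, n_v) cell-vertex adjacency
    Z: np.ndarray         # vertices per cell
    link_flipped: np.ndarray  # edges whose link sign was flipped to fix F > 0


@dataclass
class ReducedIncidence:
    """Incidence matrices with peripheral rows/columns zeroed.

    Zeroed rows and columns are retained in place so that cochains keep
    full-length storage; ``retained_*`` index sets allow the zero blocks to
    be dropped in linear solves.
    """

    A_hat: sp.csr_matrix
    B_hat: sp.csr_matrix
    retained_edges: np.ndarray
    retained_vertices: np.ndarray
    retained_links: np.ndarray


@dataclass
class MetricOperators:
    """Diagonal Hodge weights over the reduced networks.

    ``E_hat``: triangle areas at interior vertices; ``H``: cell areas;
    ``T_e_hat = diag(t_j^2/F_j)`` and ``T_l_hat = diag(T_j^2/F_j)`` over
    interior edges.  Entries at suppressed elements are zero.
    """

    E_hat: np.ndarray
    H: np.ndarray
    T_e_hat: np.ndarray
    T_l_hat: np.ndarray
    retained_edges: np.ndarray
    retained_vertices: np.ndarray


def _edge_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def build_topology(cells: list[list[int]]) -> MonolayerTopology:
    """Construct signed incidence matrices from ordered vertex cycles.

    Parameters
    ----------
    cells:
        One vertex cycle per cell, consistently wound (clockwise, i.e.
        negative shoelace once coordinates are attached), confluent:
        shared borders list the same vertices.

    Raises
    ------
    TopologyError
        if an edge belongs to three or more cells.
    OrientationError
        if two cells traverse a shared edge in the same direction.
    ConnectivityError
        if the vertex-edge graph is disconnected.
    """
    cells = [list(map(int, cyc)) for cyc in cells]
    for cyc in cells:
        if len(cyc) < 3:
            raise TopologyError(f"cell with fewer than 3 vertices: {cyc}")
        if len(set(cyc)) != len(cyc):
            raise TopologyError(f"cell cycle revisits a vertex: {cyc}")

    n_vertices = max(max(cyc) for cyc in cells) + 1
    edge_index: dict[tuple[int, int], int] = {}
    edge_verts: list[tuple[int, int]] = []
    # rows of B in triplet form
    b_rows: list[int] = []
    b_cols: list[int] = []
    b_vals: list[int] = []
    edge_cells: dict[int, list[int]] = {}

    for ci, cyc in enumerate(cells):
        n = len(cyc)
        for s in range(n):
            va, vb = cyc[s], cyc[(s + 1) % n]
            if va == vb:
                raise TopologyError("zero-length cycle step")
            key = _edge_key(va, vb)
            if key not in edge_index:
                edge_index[key] = len(edge_verts)
                edge_verts.append((va, vb))  # orientation: first traversal
            j = edge_index[key]
            tail, head = edge_verts[j]
            sign = 1 if (va, vb) == (tail, head) else -1
            prior = edge_cells.setdefault(j, [])
            if len(prior) >= 2:
                raise TopologyError(f"edge {key} incident to >2 cells")
            if prior and b_vals[prior[-1]] == sign:
                raise OrientationError(
                    f"cells traverse edge {key} in the same direction; "
                    "check winding consistency"
                )
            prior.append(len(b_vals))
            b_rows.append(ci)
            b_cols.append(j)
            b_vals.append(sign)

    n_edges = len(edge_verts)
    n_cells = len(cells)
    edge_vertices = np.asarray(edge_verts, dtype=np.int64)

    A = sp.csr_matrix(
        (
            np.concatenate([np.full(n_edges, -1), np.full(n_edges, 1)]).astype(np.int64),
            (
                np.concatenate([np.arange(n_edges)] * 2),
                np.concatenate([edge_vertices[:, 0], edge_vertices[:, 1]]),
            ),
        ),
        shape=(n_edges, n_vertices),
    )
    B = sp.csr_matrix(
        (np.asarray(b_vals, dtype=np.int64), (b_rows, b_cols)),
        shape=(n_cells, n_edges),
    )

    # connectivity over the vertex graph
    n_comp, _ = sp.csgraph.connected_components(
        sp.csr_matrix((np.ones(n_edges), (edge_vertices[:, 0], edge_vertices[:, 1])),
                      shape=(n_vertices, n_vertices)),
        directed=False,
    )
    if n_comp != 1:
        raise ConnectivityError(f"network has {n_comp} components")

    cells_per_edge = np.asarray(np.abs(B).sum(axis=0)).ravel()
    peripheral_edges = np.nonzero(cells_per_edge == 1)[0]
    peripheral_vertices = np.unique(edge_vertices[peripheral_edges].ravel())

    chi = n_vertices - n_edges + n_cells
    n_holes = 1 - chi

    boundaries = _boundary_cycles(edge_vertices, peripheral_edges)
    if len(boundaries) != n_holes + 1:
        raise TopologyError(
            f"boundary cycle count {len(boundaries)} inconsistent with "
            f"Euler characteristic ({n_holes} holes expected)"
        )
    # outer boundary: the cycle with the most edges is a robust proxy before
    # geometry exists; callers with coordinates can reclassify if needed.
    boundaries.sort(key=len, reverse=True)
    outer, holes = boundaries[0], boundaries[1:]

    return MonolayerTopology(
        n_vertices=n_vertices,
        n_edges=n_edges,
        n_cells=n_cells,
        A=A,
        B=B,
        cells=cells,
        edge_vertices=edge_vertices,
        peripheral_edges=peripheral_edges,
        peripheral_vertices=peripheral_vertices,
        n_holes=n_holes,
        hole_boundaries=holes,
        outer_boundary=outer,
    )


def _boundary_cycles(edge_vertices: np.ndarray, peripheral: np.ndarray) -> list[list[int]]:
    """Group peripheral edges into closed cycles (one per boundary loop)."""
    if len(peripheral) == 0:
        return []
    incident: dict[int, list[int]] = {}
    for j in peripheral:
        for v in edge_vertices[j]:
            incident.setdefault(int(v), []).append(int(j))
    unused = set(int(j) for j in peripheral)
    cycles: list[list[int]] = []
    while unused:
        j0 = next(iter(unused))
        cycle = [j0]
        unused.discard(j0)
        v = int(edge_vertices[j0, 1])
        while True:
            nxt = [j for j in incident[v] if j in unused]
            if not nxt:
                break
            j = nxt[0]
            unused.discard(j)
            cycle.append(j)
            a, b = edge_vertices[j]
            v = int(b) if int(a) == v else int(a)
        cycles.append(cycle)
    return cycles


def euler_characteristic(topology: MonolayerTopology) -> int:
    """``N_v - N_e + N_c``; equals ``1 - n_holes`` for a valid monolayer."""
    return topology.n_vertices - topology.n_edges + topology.n_cells


def reduce_incidence(topology: MonolayerTopology) -> ReducedIncidence:
    """Zero peripheral rows/columns of A and B, keeping ``B_hat A_hat = 0``.

    Hole boundaries created by ablation bound a single cell, so they are
    classified peripheral and suppressed like the outer boundary.
    """
    e_mask = np.ones(topology.n_edges, dtype=np.int64)
    e_mask[topology.peripheral_edges] = 0
    v_mask = np.ones(topology.n_vertices, dtype=np.int64)
    v_mask[topology.peripheral_vertices] = 0
    D_e = sp.diags(e_mask, dtype=np.int64)
    D_v = sp.diags(v_mask, dtype=np.int64)
    A_hat = (D_e @ topology.A @ D_v).tocsr()
    A_hat.eliminate_zeros()
    B_hat = (topology.B @ D_e).tocsr()
    B_hat.eliminate_zeros()

    return ReducedIncidence(
        A_hat=A_hat,
        B_hat=B_hat,
        retained_edges=topology.interior_edges,
        retained_vertices=topology.interior_vertices,
        retained_links=topology.interior_edges,
    )


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def compute_geometry(topology: MonolayerTopology, r: np.ndarray) -> MonolayerGeometry:
    """Populate all metric quantities from vertex positions.

    Peripheral links run from the edge centroid to the single adjacent cell
    centre; triangles around peripheral vertices use those centroids as
    corners.  Link signs are flipped where needed so that every interior
    parallelogram area ``F_j`` is positive.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (topology.n_vertices, 2):
        raise ValueError(f"positions shape {r.shape} != ({topology.n_vertices}, 2)")

    A, B = topology.A, topology.B
    ev = topology.edge_vertices

    t = r[ev[:, 1]] - r[ev[:, 0]]
    t_len = np.linalg.norm(t, axis=1)
    if np.any(t_len <= 0):
        raise DegenerateGeometryError("zero-length edge")

    C_adj = (abs(B) @ abs(A)).tocsr()  # face-vertex adjacency (x2)
    C_adj.data //= 2
    Z = np.asarray(C_adj.sum(axis=1)).ravel().astype(np.int64)
    R = np.asarray(C_adj @ r) / Z[:, None]

    c = 0.5 * (r[ev[:, 0]] + r[ev[:, 1]])

    # clockwise winding: signed shoelace area is negative, A_i = -shoelace
    A_cell = np.empty(topology.n_cells)
    for i, cyc in enumerate(topology.cells):
        A_cell[i] = -_polygon_area(r[cyc])
    if np.any(A_cell <= 0):
        bad = np.nonzero(A_cell <= 0)[0]
        raise OrientationError(f"non-clockwise cells (areas <= 0): {bad.tolist()}")

    # links: interior T_j = sum_i B_ij R_i; peripheral T_j = B_ij (R_i - c_j)
    T = np.asarray(B.T @ R)
    peri = topology.peripheral_edges
    if len(peri):
        Bp = B.tocsc()[:, peri]
        sgn = np.asarray(Bp.sum(axis=0)).ravel()  # the single B_ij
        T[peri] -= sgn[:, None] * c[peri]

    eps_t = t @ EPS_I.T
    F = np.einsum("jd,jd->j", T, eps_t)
    link_flipped = np.nonzero(F < 0)[0]
    if len(link_flipped):
        T[link_flipped] *= -1
        F[link_flipped] *= -1
    interior = topology.interior_edges
    if np.any(F[interior] <= 0):
        raise OrientationError("non-positive F_j on an interior edge")
    T_len = np.linalg.norm(T, axis=1)

    # edge-line / link-line intersection b_j
    b = _line_intersections(c, T, r[ev[:, 0]], t)

    E_tri = _triangle_areas(topology, r, R, c)

    return MonolayerGeometry(
        r=r, R=R, t=t, T=T, c=c, b=b,
        A_cell=A_cell, E_tri=E_tri, F=F,
        t_len=t_len, T_len=T_len,
        C_adj=C_adj, Z=Z, link_flipped=link_flipped,
    )


def _line_intersections(c: np.ndarray, T: np.ndarray,
                        p0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Intersection of the infinite edge line (p0 + s t) with the link line
    through c along T; falls back to the edge centroid for parallel lines."""
    cross = T[:, 0] * t[:, 1] - T[:, 1] * t[:, 0]
    b = c.copy()
    ok = np.abs(cross) > 1e-14 * np.maximum(np.linalg.norm(T, axis=1) *
                                            np.linalg.norm(t, axis=1), 1e-300)
    d = c - p0
    # solve p0 + s t = c + u T by Cramer's rule
    s = T[:, 0] * d[:, 1] - T[:, 1] * d[:, 0]
    s = np.where(ok, s / np.where(ok, cross, 1.0), 0.5)
    b[ok] = p0[ok] + s[ok, None] * t[ok]
    return b


def _triangle_areas(topology: MonolayerTopology, r: np.ndarray,
                    R: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Area of the polygon of incident cell centres around each vertex.

    At peripheral vertices the centroids of the incident peripheral edges
    complete the polygon; corners are ordered by angle about the vertex.
    """
    n_v = topology.n_vertices
    E_tri = np.zeros(n_v)
    cells_of_vertex: list[list[int]] = [[] for _ in range(n_v)]
    for i, cyc in enumerate(topology.cells):
        for k in cyc:
            cells_of_vertex[k].append(i)
    peri_edges_of_vertex: dict[int, list[int]] = {}
    for j in topology.peripheral_edges:
        for v in topology.edge_vertices[j]:
            peri_edges_of_vertex.setdefault(int(v), []).append(int(j))

    peripheral = set(int(v) for v in topology.peripheral_vertices)
    for k in range(n_v):
        pts = [R[i] for i in cells_of_vertex[k]]
        if k in peripheral:
            pts += [c[j] for j in peri_edges_of_vertex.get(k, [])]
        if len(pts) < 3:
            continue
        P = np.asarray(pts) - r[k]
        order = np.argsort(np.arctan2(P[:, 1], P[:, 0]))
        E_tri[k] = abs(_polygon_area(np.asarray(pts)[order]))
    return E_tri


def metric_operators(geometry: MonolayerGeometry,
                     reduced: ReducedIncidence) -> MetricOperators:
    """Diagonal Hodge weights restricted to retained elements.

    ``T_e_hat * T_l_hat = (t T / F)^2 >= 1`` per edge, with equality (so
    ``T_e_hat = T_l_hat^{-1}``) exactly when edges and links are orthogonal.
    """
    re = reduced.retained_edges
    rv = reduced.retained_vertices
    if np.any(geometry.F[re] == 0):
        raise DegenerateGeometryError("vanishing parallelogram area F_j")
    n_e = len(geometry.F)
    n_v = len(geometry.E_tri)
    T_e = np.zeros(n_e)
    T_l = np.zeros(n_e)
    T_e[re] = geometry.t_len[re] ** 2 / geometry.F[re]
    T_l[re] = geometry.T_len[re] ** 2 / geometry.F[re]
    E_hat = np.zeros(n_v)
    E_hat[rv] = geometry.E_tri[rv]
    if np.any(E_hat[rv] <= 0):
        raise DegenerateGeometryError("non-positive triangle area at interior vertex")
    H = geometry.A_cell.copy()
    return MetricOperators(E_hat=E_hat, H=H, T_e_hat=T_e, T_l_hat=T_l,
                           retained_edges=re, retained_vertices=rv)
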