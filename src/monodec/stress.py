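"""Rotated force potential, cell stress tensors and ablation differencing.

At equilibrium the three corner forces meeting at each vertex sum to
zero; rotating every corner force ``f_ik`` by the quarter turn ``eps_i``
therefore builds closed triangles around vertices and closed polygons
around cells.  Integrating these rotated forces over the edge-centroid
network yields a vector potential ``h_j``, one 2D vector per edge, with

    -sum_j B_ij A_jk h_j = eps_i f_ik

(the discrete analogue of the Airy/Mindlin stress functions).  Under zero
external load the potential vanishes along peripheral edges, which fixes
the gauge.  The cell stress tensor follows as

    sigma_i = A_i^{-1} sum_j B_ij (t_j x h_j) eps_i

with shear stress ``zeta_i = sqrt(-det sigma_i^Ds)`` from the symmetric
deviatoric part and effective pressure ``P_eff,i = tr(sigma_i)/2``,
which equals ``-cocurl^c h / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dec import EdgeVectorField
from .mesh import EPS_I
from .monolayer import Monolayer
from .operators import curl
from .vertex_model import SimulationState, VertexModelParams, corner_forces

__all__ = [
    "RotatedForcePotential",
    "CellStress",
    "rotated_force_potential",
    "cell_stress",
    "ablation_response",
    "upper_bound_slope",
]


class EquilibriumError(RuntimeError):
    """State is not in force balance; the potential is path-dependent."""


@dataclass
class RotatedForcePotential:
    """Edge-indexed rotated-force potential ``h_j``."""

    h: np.ndarray                  # (n_edges, 2)
    closure_residual: float        # max loop defect during integration
    peripheral_max: float          # max |h_j| over peripheral edges

    def as_field(self) -> EdgeVectorField:
        return EdgeVectorField("edges", self.h)


@dataclass
class CellStress:
    """Per-cell stress tensor and its invariants."""

    sigma: np.ndarray      # (n_cells, 2, 2)
    sigma_Ds: np.ndarray   # symmetric deviatoric part
    sigma_Da: np.ndarray   # antisymmetric deviatoric part
    zeta: np.ndarray       # shear stress >= 0
    P_eff: np.ndarray      # effective pressure, tr(sigma)/2
    clip_events: int       # times -det(sigma_Ds) < 0 was clipped to 0


def rotated_force_potential(state: SimulationState,
                            params: VertexModelParams,
                            tol: float | None = None) -> RotatedForcePotential:
    """Integrate rotated corner forces into the edge potential ``h``.

    Within each cell, walking its boundary clockwise, consecutive edges
    differ by the rotated corner force at the shared vertex
    (``h_out = h_in + eps_i f_ik``).  A breadth-first sweep over cells
    propagates values from a peripheral edge gauged to zero;
    path-independence (loop closure) holds at equilibrium and its defect
    is reported.  Raises :class:`EquilibriumError` if the closure defect
    exceeds ``tol`` (default ``1e3 * force_tol``).
    """
    mono = state.monolayer()
    top = mono.topology
    cid, vid, f = corner_forces(state, params)
    frot = f @ EPS_I.T

    # map (cell, vertex) -> rotated force
    fmap: dict[tuple[int, int], np.ndarray] = {
        (int(i), int(k)): frot[c] for c, (i, k) in enumerate(zip(cid, vid))
    }

    # per cell: ordered edge list with shared vertices between consecutive
    # edges, following the stored winding
    edge_of = {}
    for j, (a, b) in enumerate(top.edge_vertices):
        edge_of[(int(a), int(b))] = j
        edge_of[(int(b), int(a))] = j
    cell_edges: list[list[tuple[int, int]]] = []  # (edge, vertex entering it)
    for cyc in top.cells:
        n = len(cyc)
        seq = []
        for s in range(n):
            va, vb = cyc[s], cyc[(s + 1) % n]
            seq.append((edge_of[(va, vb)], va))  # edge starts at va
        cell_edges.append(seq)

    n_e = top.n_edges
    h = np.full((n_e, 2), np.nan)
    # start from a peripheral edge at zero; if none (torus-like; not
    # expected) start anywhere
    start = int(top.peripheral_edges[0]) if len(top.peripheral_edges) else 0
    h[start] = 0.0
    closure = 0.0

    # BFS over cells: a cell with any known edge determines all its edges
    known_cells = set()
    pending = True
    while pending:
        pending = False
        for i, seq in enumerate(cell_edges):
            if i in known_cells:
                continue
            known = [s for s, (j, _) in enumerate(seq) if not np.isnan(h[j, 0])]
            if not known:
                continue
            pending = True
            known_cells.add(i)
            n = len(seq)
            s0 = known[0]
            for step in range(1, n + 1):
                s_prev = (s0 + step - 1) % n
                s_cur = (s0 + step) % n
                j_prev = seq[s_prev][0]
                j_cur, v_shared = seq[s_cur]
                inc = fmap[(i, v_shared)]
                val = h[j_prev] + inc
                if np.isnan(h[j_cur, 0]):
                    h[j_cur] = val
                else:
                    closure = max(closure, float(np.abs(h[j_cur] - val).max()))
    if np.isnan(h).any():
        raise RuntimeError("rotated-force network did not connect all edges")

    tol = (1e3 * params.force_tol) if tol is None else tol
    if closure > tol:
        raise EquilibriumError(
            f"loop closure defect {closure:.3e} exceeds {tol:.3e}; "
            "state is not equilibrated")
    peri = top.peripheral_edges
    peri_max = float(np.linalg.norm(h[peri], axis=1).max()) if len(peri) else 0.0
    return RotatedForcePotential(h=h, closure_residual=closure,
                                 peripheral_max=peri_max)


def cell_stress(state: SimulationState, h: np.ndarray | RotatedForcePotential
                ) -> CellStress:
    """Cell stress tensors from the rotated force potential."""
    if isinstance(h, RotatedForcePotential):
        h = h.h
    mono = state.monolayer()
    top, g = mono.topology, mono.geometry
    B = top.B.tocoo()
    sigma = np.zeros((top.n_cells, 2, 2))
    outer = np.einsum("ja,jb->jab", g.t, h)  # t_j (x) h_j
    np.add.at(sigma, B.row, B.data[:, None, None] * outer[B.col])
    sigma = sigma @ EPS_I / g.A_cell[:, None, None]

    tr = sigma[:, 0, 0] + sigma[:, 1, 1]
    P_eff = 0.5 * tr
    dev = sigma - 0.5 * tr[:, None, None] * np.eye(2)
    Ds = 0.5 * (dev + np.transpose(dev, (0, 2, 1)))
    Da = 0.5 * (dev - np.transpose(dev, (0, 2, 1)))
    det = Ds[:, 0, 0] * Ds[:, 1, 1] - Ds[:, 0, 1] * Ds[:, 1, 0]
    clip = int(np.sum(-det < 0))
    zeta = np.sqrt(np.clip(-det, 0.0, None))
    return CellStress(sigma=sigma, sigma_Ds=Ds, sigma_Da=Da, zeta=zeta,
                      P_eff=P_eff, clip_events=clip)


def effective_pressure_from_curl(state: SimulationState,
                                 h: np.ndarray | RotatedForcePotential
                                 ) -> np.ndarray:
    """Second route to ``P_eff``: ``-cocurl^c h / 2``."""
    if isinstance(h, RotatedForcePotential):
        h = h.h
    mono = state.monolayer()
    cc = curl(mono, EdgeVectorField("edges", h))
    return -0.5 * cc.values[:, 0]


def ablation_response(pre: SimulationState, post: SimulationState,
                      params: VertexModelParams | None = None) -> dict:
    """Per-cell stress and displacement changes caused by an ablation.

    Cells are matched through the ablation events recorded in ``post``;
    distances are measured from the centroid of the removed cells in the
    pre-ablation state.  Returns per-surviving-cell arrays of
    ``|delta zeta|``, ``|delta P_eff|``, centre displacements and their
    normalised radial components.
    """
    if params is None:
        params = VertexModelParams()
    removed: list[int] = []
    n_before = len(pre.cells)
    for ev in post.events:
        if ev[0] == "ablate":
            removed.extend(ev[1])
    if not removed:
        raise ValueError("post state records no ablation event")
    from .vertex_model import surviving_cell_map

    cmap = surviving_cell_map(tuple(removed), n_before)

    mono_pre = pre.monolayer()
    center = np.mean([mono_pre.geometry.R[i] for i in removed], axis=0)

    hp = rotated_force_potential(pre, params)
    sp = cell_stress(pre, hp)
    hq = rotated_force_potential(post, params)
    sq = cell_stress(post, hq)

    old_ids = np.array(sorted(cmap.keys()))
    new_ids = np.array([cmap[i] for i in old_ids])
    R_pre = mono_pre.geometry.R[old_ids]
    R_post = post.monolayer().geometry.R[new_ids]
    dR = R_post - R_pre
    rel = R_pre - center
    radius = np.linalg.norm(rel, axis=1)
    rhat = rel / np.where(radius > 0, radius, 1.0)[:, None]
    dnorm = np.linalg.norm(dR, axis=1)
    radial = np.einsum("id,id->i", dR / np.where(dnorm > 0, dnorm, 1.0)[:, None],
                       rhat)

    peri_cells = _peripheral_cells(mono_pre)
    return {
        "cell_pre": old_ids,
        "cell_post": new_ids,
        "center": center,
        "radius": radius,
        "d_zeta": np.abs(sq.zeta[new_ids] - sp.zeta[old_ids]),
        "d_P_eff": np.abs(sq.P_eff[new_ids] - sp.P_eff[old_ids]),
        "displacement": dR,
        "displacement_norm": dnorm,
        "radial_component": radial,
        "peripheral": np.isin(old_ids, peri_cells),
        "zeta_pre": sp.zeta[old_ids],
        "P_eff_pre": sp.P_eff[old_ids],
    }


def _peripheral_cells(mono: Monolayer) -> np.ndarray:
    B = abs(mono.topology.B.tocsc())
    peri = mono.topology.peripheral_edges
    if not len(peri):
        return np.array([], dtype=int)
    mask = np.asarray(B[:, peri].sum(axis=1)).ravel() > 0
    return np.nonzero(mask)[0]


def upper_bound_slope(values: np.ndarray, radii: np.ndarray,
                      n_bins: int = 12, r_max_frac: float = 0.8,
                      min_points: int = 3) -> tuple[float, float]:
    """Log-log slope of the radial upper envelope of a positive field.

    Radii are binned logarithmically between the innermost bin holding at
    least ``min_points`` points and ``r_max_frac`` of the maximum radius
    (excluding the periphery); the per-bin maxima are fitted by ordinary
    least squares in log10-log10.  Returns ``(slope, stderr)``.
    """
    values = np.asarray(values, dtype=float)
    radii = np.asarray(radii, dtype=float)
    keep = (radii > 0) & (values > 0)
    values, radii = values[keep], radii[keep]
    if len(values) < 2 * n_bins:
        raise ValueError("not enough points for the requested binning")
    r_hi = r_max_frac * radii.max()
    r_lo = radii.min()
    edges = np.geomspace(r_lo, r_hi, n_bins + 1)
    which = np.digitize(radii, edges) - 1
    centers, maxima = [], []
    for b in range(n_bins):
        sel = which == b
        if np.sum(sel) >= min_points:
            centers.append(np.sqrt(edges[b] * edges[b + 1]))
            maxima.append(values[sel].max())
    if len(centers) < 5:
        raise ValueError(f"only {len(centers)} populated bins; need >= 5")
    x = np.log10(centers)
    y = np.log10(maxima)
    n = len(x)
    X = np.stack([np.ones(n), x], axis=1)
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    dof = max(n - 2, 1)
    s2 = float(np.sum((y - yhat) ** 2)) / dof
    sxx = float(np.sum((x - x.mean()) ** 2))
    stderr = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.inf
    return float(coef[1]), stderr
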