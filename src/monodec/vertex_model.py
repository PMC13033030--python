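"""Quadratic-energy vertex model: growth, relaxation, T1s and ablation.

Vertices flow down the gradient of

    E = 1/2 sum_i [ (A_i - 1)^2 + Gamma (L_i - L0~)^2 ] - sigma_p sum_i A_i

with cell areas ``A_i`` and perimeters ``L_i`` in units of the preferred
cell area; ``Gamma`` weights perimeter against bulk elasticity, ``L0~`` is
the dimensionless preferred perimeter and ``sigma_p`` an isotropic stress
applied at the monolayer periphery (zero for all analysis runs).  The
defaults ``Gamma = 0.2``, ``L0~ = 0.75`` keep monolayers rigid.

Monolayers are grown from a single hexagon by random division: a randomly
chosen cell is cut along a uniformly random axis through its centroid and
the system re-relaxed, with T1 neighbour exchanges whenever an interior
edge shortens below threshold.  Growth locks heterogeneous prestress into
the tissue.  Ablation removes interior cells, punching holes that change
the domain topology, followed by relaxation.

All randomness flows through one seeded generator and every division, T1
and ablation is recorded in the event log, so runs replay exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import EPS_I
from .monolayer import Monolayer

__all__ = [
    "VertexModelParams",
    "SimulationState",
    "vertex_energy",
    "vertex_forces",
    "corner_forces",
    "relax",
    "t1_transition",
    "divide_cell",
    "grow_monolayer",
    "ablate",
    "regular_hexagon_state",
]


@dataclass
class VertexModelParams:
    """Mechanical and numerical parameters of the vertex model."""

    gamma: float = 0.2
    l0_tilde: float = 0.75
    peripheral_stress: float = 0.0
    dt_init: float = 0.05
    dt_max: float = 0.5
    force_tol: float = 1e-8
    t1_threshold: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0 or self.force_tol <= 0 or self.t1_threshold < 0:
            raise ValueError("gamma, force_tol must be > 0; t1_threshold >= 0")


class _CornerData:
    """Flattened per-corner index arrays for vectorized energy/forces."""

    def __init__(self, cells: list[list[int]], n_vertices: int):
        idx, cid, prv, nxt = [], [], [], []
        for i, cyc in enumerate(cells):
            n = len(cyc)
            base = len(idx)
            idx.extend(cyc)
            cid.extend([i] * n)
            prv.extend(base + (np.arange(n) - 1) % n)
            nxt.extend(base + (np.arange(n) + 1) % n)
        self.vertex = np.asarray(idx, dtype=np.int64)
        self.cell = np.asarray(cid, dtype=np.int64)
        self.prev = np.asarray(prv, dtype=np.int64)
        self.next = np.asarray(nxt, dtype=np.int64)
        self.n_cells = len(cells)
        self.n_vertices = n_vertices
        # undirected edges and their cell multiplicity, for T1 scanning
        seen: dict[tuple[int, int], list[int]] = {}
        for corner, (v, i) in enumerate(zip(self.vertex, self.cell)):
            w = self.vertex[self.next[corner]]
            key = (v, w) if v < w else (w, v)
            seen.setdefault(key, []).append(i)
        self.edges = np.asarray(list(seen.keys()), dtype=np.int64)
        self.edge_ncells = np.asarray([len(v) for v in seen.values()])
        counts = np.bincount(self.vertex, minlength=n_vertices)
        self.vertex_valence = counts


@dataclass
class SimulationState:
    """Cell cycles + vertex positions + event log."""

    cells: list[list[int]]
    r: np.ndarray
    time: float = 0.0
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self._corners: _CornerData | None = None

    @property
    def corners(self) -> _CornerData:
        if self._corners is None:
            self._corners = _CornerData(self.cells, len(self.r))
        return self._corners

    def invalidate(self) -> None:
        self._corners = None

    def monolayer(self) -> Monolayer:
        return Monolayer(self.cells, self.r)

    def copy(self) -> "SimulationState":
        return SimulationState([list(c) for c in self.cells], self.r.copy(),
                               self.time, list(self.events))


def regular_hexagon_state(area: float = 1.0) -> SimulationState:
    """Single regular hexagonal cell of given area, clockwise winding."""
    side = np.sqrt(2.0 * area / (3.0 * np.sqrt(3.0)))
    ang = np.pi / 6 - np.arange(6) * np.pi / 3
    r = side * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return SimulationState(cells=[list(range(6))], r=r)


def _cell_measures(state: SimulationState) -> tuple[np.ndarray, np.ndarray]:
    c = state.corners
    r = state.r
    pk, pn = r[c.vertex], r[c.vertex[c.next]]
    cross = pk[:, 0] * pn[:, 1] - pk[:, 1] * pn[:, 0]
    # clockwise winding: signed shoelace negative, A_i = -shoelace
    A = -0.5 * np.bincount(c.cell, weights=cross, minlength=c.n_cells)
    seg = np.linalg.norm(pn - pk, axis=1)
    L = np.bincount(c.cell, weights=seg, minlength=c.n_cells)
    return A, L


def vertex_energy(state: SimulationState, params: VertexModelParams) -> float:
    A, L = _cell_measures(state)
    E = 0.5 * np.sum((A - 1.0) ** 2 + params.gamma * (L - params.l0_tilde) ** 2)
    return float(E - params.peripheral_stress * A.sum())


def _corner_force_arrays(state: SimulationState, params: VertexModelParams
                         ) -> np.ndarray:
    """Per-corner force contribution of each cell on its vertex."""
    c = state.corners
    r = state.r
    A, L = _cell_measures(state)
    pk = r[c.vertex]
    pprev = r[c.vertex[c.prev]]
    pnext = r[c.vertex[c.next]]
    # dA_i/dr_k for clockwise cells: 0.5 * (y_prev - y_next, x_next - x_prev)
    dA = 0.5 * np.stack([pprev[:, 1] - pnext[:, 1],
                         pnext[:, 0] - pprev[:, 0]], axis=1)
    e_prev = pk - pprev
    e_next = pnext - pk
    len_prev = np.maximum(np.linalg.norm(e_prev, axis=1), 1e-300)
    len_next = np.maximum(np.linalg.norm(e_next, axis=1), 1e-300)
    dL = e_prev / len_prev[:, None] - e_next / len_next[:, None]
    coefA = A[c.cell] - 1.0 - params.peripheral_stress
    coefL = params.gamma * (L[c.cell] - params.l0_tilde)
    return -(coefA[:, None] * dA + coefL[:, None] * dL)


def corner_forces(state: SimulationState, params: VertexModelParams
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-(cell, vertex) forces ``f_ik``.

    Returns ``(cell_index, vertex_index, force)`` arrays; summing forces
    per vertex gives the net vertex force, and both the per-vertex and the
    per-cell sums vanish at equilibrium (closed force triangles and
    polygons of the rotated-force construction).
    """
    c = state.corners
    f = _corner_force_arrays(state, params)
    return c.cell.copy(), c.vertex.copy(), f


def vertex_forces(state: SimulationState, params: VertexModelParams
                  ) -> np.ndarray:
    """Net force per vertex, ``-dE/dr_k``."""
    c = state.corners
    f = _corner_force_arrays(state, params)
    out = np.zeros_like(state.r)
    np.add.at(out, c.vertex, f)
    return out


def _min_interior_edge(state: SimulationState) -> tuple[float, int]:
    c = state.corners
    interior = c.edge_ncells == 2
    if not interior.any():
        return np.inf, -1
    ev = c.edges[interior]
    lens = np.linalg.norm(state.r[ev[:, 0]] - state.r[ev[:, 1]], axis=1)
    k = int(np.argmin(lens))
    full_idx = np.nonzero(interior)[0][k]
    return float(lens[k]), int(full_idx)


def relax(state: SimulationState, params: VertexModelParams,
          force_tol: float | None = None, max_steps: int = 200_000,
          method: str = "fire", allow_t1: bool = True,
          strict: bool = True, patience: int | None = None) -> SimulationState:
    """Evolve ``r`` down the energy gradient until ``max|F| <= force_tol``.

    ``method='fire'`` (default) alternates a deterministic quasi-Newton
    descent at fixed topology with bounded bursts of the FIRE explicit
    integrator, which executes T1 neighbour exchanges the moment an edge
    shortens below threshold and escapes configurations where a frozen
    topology is inconsistent (inverted polygons, collapsing edges).  For
    tolerances near the double-precision energy floor a final burst of
    pure gradient dynamics (which compares forces, not energies)
    certifies the force criterion.  ``method='gd'`` is plain
    adaptive-step gradient descent (halve the step on energy increase,
    grow on success) with the same T1 handling.

    Raises ``RuntimeError`` on step underflow or exhausted budget.
    """
    tol = params.force_tol if force_tol is None else force_tol
    state = state.copy()
    try:
        if method == "fire":
            _relax_hybrid(state, params, tol, max_steps, allow_t1, patience)
        elif method == "fire_burst":
            # bounded explicit relaxation with a quasi-Newton rescue;
            # used between growth divisions where full convergence is
            # not required and FIRE's annealing dynamics are wanted
            try:
                _relax_fire(state, params, tol, max_steps, allow_t1, patience)
            except RuntimeError:
                _polish_lbfgs(state, params, tol)
                fmax = np.linalg.norm(
                    vertex_forces(state, params), axis=1).max(initial=0.0)
                if fmax > tol:
                    raise
        elif method == "gd":
            _relax_gd(state, params, tol, max_steps, allow_t1)
        else:
            raise ValueError(f"unknown method {method!r}")
    except RuntimeError:
        if strict:
            raise
        state.events.append(("relax_budget", max_steps))
    return state


def _relax_hybrid(state, params, tol, max_steps, allow_t1, patience):
    burst = min(max_steps, 4000)
    burst_patience = patience if patience is not None else 800
    for _round in range(60):
        ok = _polish_lbfgs(state, params, tol)
        fmax = np.linalg.norm(
            vertex_forces(state, params), axis=1).max(initial=0.0)
        if ok and fmax <= tol:
            # exchange any sub-threshold edge the polish created and
            # re-relax; an equilibrium short edge with no admissible
            # exchange is legitimate and accepted
            ln, _ = _min_interior_edge(state)
            if (allow_t1 and ln < params.t1_threshold
                    and _maybe_t1(state, params)):
                continue
            return
        # explicit burst: event handling (T1s) and escape from states
        # the frozen-topology polish cannot descend through
        try:
            _relax_fire(state, params, max(tol, 1e-6), burst, allow_t1,
                        burst_patience)
        except RuntimeError:
            pass
        if tol < 1e-6:
            # force-only tail for tolerances at the energy floor, where
            # energy-difference line searches cannot resolve progress;
            # convergence here is limited by the softest mode, so allow
            # a long leash
            try:
                _relax_fire(state, params, tol, min(max_steps, 60_000),
                            allow_t1, max(burst_patience, 5_000))
            except RuntimeError:
                pass
        fmax = np.linalg.norm(
            vertex_forces(state, params), axis=1).max(initial=0.0)
        if fmax <= tol:
            ln, _ = _min_interior_edge(state)
            if (allow_t1 and ln < params.t1_threshold
                    and _maybe_t1(state, params)):
                continue
            return
    fmax = np.linalg.norm(
        vertex_forces(state, params), axis=1).max(initial=0.0)
    if fmax > tol:
        raise RuntimeError(
            f"relaxation did not reach tol {tol} (max|F|={fmax:.3e})")


def _polish_lbfgs(state: SimulationState, params: VertexModelParams,
                  tol: float) -> bool:
    """Quasi-Newton refinement of vertex positions at fixed topology.

    Returns False (and restores the input positions) if the step
    inverted a cell polygon — the frozen-topology assumption failed and
    the caller should fall back to the explicit integrator.
    """
    from scipy.optimize import minimize

    shape = state.r.shape
    r0 = state.r.copy()

    def fun(x):
        state.r = x.reshape(shape)
        e = vertex_energy(state, params)
        g = -vertex_forces(state, params).ravel()
        return e, g

    res = minimize(fun, state.r.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 5_000, "gtol": 0.5 * tol,
                            "ftol": 1e-18, "maxcor": 30})
    state.r = res.x.reshape(shape)
    state.invalidate()
    A, _ = _cell_measures(state)
    if np.any(A <= 0):
        state.r = r0
        state.invalidate()
        return False
    return True


_T1_COOLDOWN = 400  # steps before the same edge may exchange again


def _maybe_t1(state: SimulationState, params: VertexModelParams,
              skipped: set | None = None,
              blocked: dict | None = None, step: int = 0) -> bool:
    """Attempt a T1 on the shortest sub-threshold interior edge.

    Edges whose exchange was skipped (boundary/valence constraints) are
    remembered in ``skipped`` and not retried until the topology changes;
    freshly exchanged edges are blocked for a cooldown window so that
    marginal configurations cannot flip back and forth indefinitely.
    """
    if params.t1_threshold <= 0:
        return False
    c = state.corners
    ev = c.edges
    if not len(ev):
        return False
    lens = np.linalg.norm(state.r[ev[:, 0]] - state.r[ev[:, 1]], axis=1)
    for k in np.argsort(lens):
        if lens[k] >= params.t1_threshold:
            return False
        edge = (int(ev[k, 0]), int(ev[k, 1]))
        # skipped edges are retried once they verge on full collapse:
        # the geometry that blocked the exchange has changed by then
        if (skipped is not None and edge in skipped
                and lens[k] > 0.05 * params.t1_threshold):
            continue
        # the cooldown (exponential backoff per edge) yields only to an
        # edge on the verge of collapsing entirely
        if (blocked is not None and blocked.get(edge, (-1, 0))[0] > step
                and lens[k] > 0.05 * params.t1_threshold):
            continue
        if t1_transition(state, edge, params):
            if skipped is not None:
                skipped.clear()
            if blocked is not None:
                count = blocked.get(edge, (0, 0))[1]
                wait = _T1_COOLDOWN * (2 ** min(count, 6))
                blocked[edge] = (step + wait, count + 1)
            return True
        # a collapsing corner of the boundary (peripheral edge whose
        # endpoint belongs to a single cell) cannot exchange; smooth it
        # away by merging the corner vertex into its neighbour
        if (lens[k] < 0.3 * params.t1_threshold
                and _collapse_boundary_spike(state, edge)):
            if skipped is not None:
                skipped.clear()
            if blocked is not None:
                blocked.clear()
            return True
        if skipped is not None:
            skipped.add(edge)
    return False


def _collapse_boundary_spike(state: SimulationState,
                             edge: tuple[int, int]) -> bool:
    """Remove a degenerate boundary corner by collapsing a peripheral edge.

    Applies when the edge belongs to a single cell and one endpoint is a
    corner vertex of that cell alone: the corner is deleted from the
    cycle, the surviving endpoint keeps its position, and vertex indices
    are compacted.  Returns False if the pattern does not apply.
    """
    a, b = edge
    cells = state.cells
    in_a = _cells_with_vertex(cells, a)
    in_b = _cells_with_vertex(cells, b)
    shared = [i for i in in_a if i in in_b]
    if len(shared) != 1:
        return False
    P = shared[0]
    if len(cells[P]) < 4:
        return False
    if len(in_a) == 1:
        corner, keep = a, b
    elif len(in_b) == 1:
        corner, keep = b, a
    else:
        return False
    cells[P].remove(corner)
    # compact vertex indices
    used = sorted({v for cyc in cells for v in cyc})
    remap = {v: i for i, v in enumerate(used)}
    state.cells = [[remap[v] for v in cyc] for cyc in cells]
    state.r = state.r[used]
    state.invalidate()
    state.events.append(("boundary_collapse", a, b))
    return True


def _relax_fire(state, params, tol, max_steps, allow_t1, patience=None):
    # FIRE: inertial descent with velocity mixing and adaptive dt
    dt = params.dt_init
    dt_max = params.dt_max
    alpha0, f_alpha, f_inc, f_dec, n_min = 0.1, 0.99, 1.1, 0.5, 5
    alpha = alpha0
    v = np.zeros_like(state.r)
    since_neg = 0
    skipped: set = set()
    blocked: dict = {}
    best_f, best_step = np.inf, 0
    F = vertex_forces(state, params)
    for step in range(max_steps):
        fmax = np.linalg.norm(F, axis=1).max(initial=0.0)
        if fmax <= tol:
            return
        if fmax < 0.99 * best_f:
            best_f, best_step = fmax, step
        elif patience is not None and step - best_step > patience:
            raise RuntimeError(
                f"force plateau at {fmax:.3e} after {step} steps")
        P = float((F * v).sum())
        if P > 0:
            since_neg += 1
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(F)
            if fn > 0:
                v = (1 - alpha) * v + alpha * (vn / fn) * F
            if since_neg > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            v[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            since_neg = 0
            if dt < 1e-14:
                raise RuntimeError("FIRE step underflow")
        v = v + dt * F
        state.r = state.r + dt * v
        state.time += dt
        if allow_t1 and _maybe_t1(state, params, skipped, blocked, step):
            v = np.zeros_like(state.r)
            dt = params.dt_init
            alpha = alpha0
            since_neg = 0
        F = vertex_forces(state, params)
    raise RuntimeError(f"relaxation did not reach tol {tol} in {max_steps} steps "
                       f"(max|F|={np.linalg.norm(F, axis=1).max():.3e})")


def _relax_gd(state, params, tol, max_steps, allow_t1):
    dt = params.dt_init
    E = vertex_energy(state, params)
    skipped: set = set()
    blocked: dict = {}
    for step in range(max_steps):
        F = vertex_forces(state, params)
        fmax = np.linalg.norm(F, axis=1).max(initial=0.0)
        if fmax <= tol:
            return
        r_new = state.r + dt * F
        r_old = state.r
        state.r = r_new
        E_new = vertex_energy(state, params)
        if E_new > E:
            state.r = r_old
            dt *= 0.5
            if dt < 1e-14:
                raise RuntimeError("gradient-descent step underflow")
            continue
        E = E_new
        state.time += dt
        dt = min(dt * 1.1, params.dt_max)
        if allow_t1 and _maybe_t1(state, params, skipped, blocked, step):
            E = vertex_energy(state, params)
            dt = params.dt_init
    raise RuntimeError(f"relaxation did not reach tol {tol} in {max_steps} steps")


def _cells_with_vertex(cells: list[list[int]], v: int) -> list[int]:
    return [i for i, cyc in enumerate(cells) if v in cyc]


def t1_transition(state: SimulationState, edge: tuple[int, int],
                  params: VertexModelParams) -> bool:
    """Neighbour exchange across a short edge.

    The edge collapses and re-expands perpendicular at 1.5x the trigger
    threshold; the two edge-sharing cells each lose the edge, the two
    vertex-sharing cells gain it.  At the monolayer boundary the exterior
    plays the role of one missing cell: an interior edge with a boundary
    endpoint can still exchange (the gaining cell reaches the boundary),
    and a collapsing peripheral edge rotates into an interior edge
    between the two pinching neighbours.  Configurations with no real
    gaining cell or with a losing triangle are skipped (returns False,
    with a log entry).
    """
    a, b = edge
    cells = state.cells
    in_a = _cells_with_vertex(cells, a)
    in_b = _cells_with_vertex(cells, b)
    shared = [i for i in in_a if i in in_b]
    # Losing cells P, Q share the edge; the exterior stands in for Q when
    # the edge itself is peripheral.  Gaining cells R (third cell of a)
    # and S (third cell of b) are absent when that endpoint lies on the
    # boundary: the exterior gains the edge on that side.
    extra_a = [i for i in in_a if i not in shared]
    extra_b = [i for i in in_b if i not in shared]
    if len(shared) == 2:
        P, Q = shared
    elif len(shared) == 1:
        P, Q = shared[0], None
    else:
        state.events.append(("t1_skipped", a, b))
        return False
    R = extra_a[0] if len(extra_a) == 1 else None
    S = extra_b[0] if len(extra_b) == 1 else None
    ok = (len(extra_a) <= 1 and len(extra_b) <= 1
          and [Q, R, S].count(None) <= 1 and (R is None or R != S))
    if ok and (len(cells[P]) < 4 or (Q is not None and len(cells[Q]) < 4)):
        ok = False
    if not ok:
        state.events.append(("t1_skipped", a, b))
        return False

    def neighbors(cyc, v):
        k = cyc.index(v)
        return cyc[(k - 1) % len(cyc)], cyc[(k + 1) % len(cyc)]

    old = {i: list(cells[i]) for i in (P, Q, R, S) if i is not None}
    old_ra, old_rb = state.r[a].copy(), state.r[b].copy()

    cells[P].remove(b)
    if Q is not None:
        cells[Q].remove(a)
    if R is not None:
        # b attaches on the side of a's neighbour shared with Q (for a
        # peripheral edge: the neighbour not shared with P)
        nR = neighbors(cells[R], a)
        if Q is not None:
            w = nR[0] if nR[0] in cells[Q] else nR[1]
        else:
            w = nR[0] if nR[0] not in cells[P] else nR[1]
        kR = cells[R].index(a)
        if cells[R][(kR + 1) % len(cells[R])] == w:
            cells[R].insert(kR + 1, b)
        else:
            cells[R].insert(kR, b)
    if S is not None:
        nS = neighbors(cells[S], b)
        p = nS[0] if nS[0] in cells[P] else nS[1]
        kS = cells[S].index(b)
        if cells[S][(kS + 1) % len(cells[S])] == p:
            cells[S].insert(kS + 1, a)
        else:
            cells[S].insert(kS, a)

    m = 0.5 * (old_ra + old_rb)
    u = old_rb - old_ra
    u /= np.linalg.norm(u)
    n = EPS_I @ u
    ell = 1.5 * max(params.t1_threshold, 1e-3)

    def areas_ok() -> bool:
        for i in (P, Q, R, S):
            if i is None:
                continue
            pts = state.r[cells[i]]
            x, y = pts[:, 0], pts[:, 1]
            if -(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) <= 0:
                return False
        return True

    # crowded neighbourhoods may not admit the nominal re-expansion
    # length; retry shorter before giving up
    for scale in (1.0, 0.5, 0.25, 0.1):
        for sign in (1.0, -1.0):
            state.r[a] = m + sign * 0.5 * scale * ell * n
            state.r[b] = m - sign * 0.5 * scale * ell * n
            if areas_ok():
                state.invalidate()
                state.events.append(("t1", a, b, float(sign)))
                return True
    # revert
    for i, cyc in old.items():
        cells[i] = cyc
    state.r[a], state.r[b] = old_ra, old_rb
    state.invalidate()
    state.events.append(("t1_failed", a, b))
    return False


def divide_cell(state: SimulationState, ci: int, angle: float) -> bool:
    """Split cell ``ci`` along a line through its centroid.

    Two new vertices are placed on the crossed edges (and inserted into
    the neighbouring cells sharing those edges); the new edge joins them.
    Returns False without modifying the state if the cut is degenerate.
    """
    cells = state.cells
    cyc = cells[ci]
    n = len(cyc)
    pts = state.r[cyc]
    centroid = pts.mean(axis=0)
    d = np.array([np.cos(angle), np.sin(angle)])
    nrm = np.array([-d[1], d[0]])
    side = (pts - centroid) @ nrm
    hits = []
    for k in range(n):
        s0, s1 = side[k], side[(k + 1) % n]
        if s0 == 0.0 or s1 == 0.0:
            return False
        if (s0 > 0) != (s1 > 0):
            t = s0 / (s0 - s1)
            if not 0.05 < t < 0.95:
                return False
            hits.append((k, t))
    if len(hits) != 2:
        return False

    new_pts = []
    for k, t in hits:
        p = (1 - t) * state.r[cyc[k]] + t * state.r[cyc[(k + 1) % n]]
        new_pts.append(p)
    base = len(state.r)
    state.r = np.vstack([state.r, np.asarray(new_pts)])
    n1, n2 = base, base + 1

    # insert new vertices into neighbour cells sharing the crossed edges
    for (k, _), nv in zip(hits, (n1, n2)):
        va, vb = cyc[k], cyc[(k + 1) % n]
        for cj, other in enumerate(cells):
            if cj == ci:
                continue
            if va in other and vb in other:
                ka, kb = other.index(va), other.index(vb)
                m = len(other)
                if (ka + 1) % m == kb:
                    other.insert(kb, nv)
                elif (kb + 1) % m == ka:
                    other.insert(ka, nv)

    # split the cycle: walk from after hit0 to hit1 inclusive
    (k0, _), (k1, _) = hits
    seg1 = [n1]
    k = (k0 + 1) % n
    while True:
        seg1.append(cyc[k])
        if k == k1:
            break
        k = (k + 1) % n
    seg1.append(n2)
    seg2 = [n2]
    k = (k1 + 1) % n
    while True:
        seg2.append(cyc[k])
        if k == k0:
            break
        k = (k + 1) % n
    seg2.append(n1)
    if len(seg1) < 3 or len(seg2) < 3:
        state.r = state.r[:base]
        return False
    cells[ci] = seg1
    cells.append(seg2)
    state.invalidate()
    state.events.append(("divide", ci, float(angle), len(cells) - 1))
    return True


def grow_monolayer(n_cells_target: int, params: VertexModelParams,
                   growth_tol: float = 1e-3,
                   growth_max_steps: int = 6_000) -> SimulationState:
    """Grow a disordered monolayer by random division from one hexagon.

    Each accepted division is followed by relaxation toward
    ``growth_tol`` under the prescribed peripheral stress (capped at
    ``growth_max_steps``; growth is a non-equilibrium process and the
    intermediate states need not be fully balanced); after the target
    count is reached the monolayer is relaxed strictly to
    ``params.force_tol`` with zero peripheral stress, ready for
    analysis.
    """
    if n_cells_target < 1:
        raise ValueError("n_cells_target >= 1")
    rng = np.random.default_rng(params.rng_seed)
    state = regular_hexagon_state()
    state.events.append(("seed", params.rng_seed))
    while len(state.cells) < n_cells_target:
        for _ in range(10):
            ci = int(rng.integers(len(state.cells)))
            angle = float(rng.uniform(0.0, np.pi))
            if divide_cell(state, ci, angle):
                break
        else:
            raise RuntimeError("could not find a valid division axis")
        state = relax(state, params, force_tol=growth_tol,
                      max_steps=growth_max_steps, strict=False,
                      patience=800, method="fire_burst")
    final = replace(params, peripheral_stress=0.0)
    state = relax(state, final, force_tol=params.force_tol,
                  max_steps=500_000)
    return state


def ablate(state: SimulationState, cell_ids: list[int],
           params: VertexModelParams | None = None,
           relax_after: bool = True) -> SimulationState:
    """Remove interior cells, creating holes, and re-relax.

    Raises ``ValueError`` if a listed cell touches the monolayer boundary
    or an existing hole.  Surviving cells keep their order; removed
    indices are recorded in the event log so pre/post states can be
    matched cell by cell.
    """
    state = state.copy()
    mono = state.monolayer()
    peri_v = set(int(v) for v in mono.topology.peripheral_vertices)
    for ci in cell_ids:
        if any(v in peri_v for v in state.cells[ci]):
            raise ValueError(f"cell {ci} touches the boundary; cannot ablate")
    removed = sorted(set(int(c) for c in cell_ids))
    state.cells = [c for i, c in enumerate(state.cells) if i not in removed]
    state.invalidate()
    state.events.append(("ablate", tuple(removed)))
    # validate the punched topology (raises if disconnected/non-manifold)
    state.monolayer()
    if relax_after:
        if params is None:
            params = VertexModelParams()
        state = relax(state, params)
    return state


def surviving_cell_map(removed: tuple[int, ...], n_cells_before: int) -> dict[int, int]:
    """Old-index -> new-index map after ablation."""
    removed_set = set(removed)
    out = {}
    new = 0
    for old in range(n_cells_before):
        if old in removed_set:
            continue
        out[old] = new
        new += 1
    return out
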