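"""Helmholtz-Hodge decomposition and harmonic fields on ablated monolayers.

A vector field on edges (or links) splits as

    v = grad phi + rot u + x

with a pair-valued potential ``phi`` on interior vertices (cell centres on
the dual network), a pair-valued potential ``u`` on cells (interior
vertices), and a harmonic remainder ``x`` that is divergence- and
curl-free.  The two Poisson problems decouple into four scalar problems
driven by the slots of ``-div v`` and ``curl v``; the reduced networks
impose homogeneous Dirichlet data on ``phi`` (and ``U``), while the
cell-centre problems are singular with the constant kernel and require
the forcing to integrate to zero (the forcing is projected onto the
operator's range and the applied correction is reported).

Harmonic fields come from the kernel of the scalar edge Laplacian
``L_E`` (link Laplacian ``L_L`` on the dual network): one scalar mode
``w^(m)`` per hole, turned into a vector field by the interior product
with a uniform amplitude pair ``(z_par, z_perp)`` and sharp:

    x^(m) = z_par sum_j w_j e_par + z_perp sum_j w_j e_perp.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dec import Cochain, EdgeVectorField, flat, interior_product, sharp
from .monolayer import Monolayer
from .operators import OperatorSet, assemble_laplacians, curl, grad, neg_div, rot

__all__ = [
    "HarmonicBasis",
    "HodgeDecomposition",
    "harmonic_basis",
    "harmonic_field",
    "harmonic_magnitude_profile",
    "helmholtz_decompose",
    "reconstruction_residual",
]


class HarmonicKernelError(RuntimeError):
    """Computed null-space dimension disagrees with the hole count."""


@dataclass
class HarmonicBasis:
    """Kernel modes of the scalar edge (or link) Laplacian.

    ``modes[m]`` is a full-length scalar cochain over edges, zero on
    peripheral edges, orthonormal under the weight ``F_j/t_j^2``
    (``F_j/T_j^2`` for the dual network) so that unit amplitudes give
    unit-norm harmonic fields.
    """

    network: str
    modes: list[np.ndarray]
    eigenvalues: np.ndarray
    null_tolerance: float

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def _mode_weight(mono: Monolayer, network: str) -> np.ndarray:
    met = mono.metric
    g = mono.geometry
    w = np.zeros(mono.n_edges)
    re = met.retained_edges
    if network == "primal":
        w[re] = g.F[re] / g.t_len[re] ** 2
    else:
        w[re] = g.F[re] / g.T_len[re] ** 2
    return w


def harmonic_basis(mono: Monolayer, ops: OperatorSet | None = None,
                   network: str = "primal",
                   rtol: float = 1e-10) -> HarmonicBasis:
    """Null space of the symmetrized edge (link) Laplacian.

    The kernel dimension must equal the number of holes; a mismatch
    signals a topology/reduction inconsistency and raises
    :class:`HarmonicKernelError`.
    """
    if ops is None:
        ops = assemble_laplacians(mono, validate=False)
    S = ops.S_E if network == "primal" else ops.S_L
    re = mono.metric.retained_edges
    Sr = S[np.ix_(re, re)].toarray()
    Sr = 0.5 * (Sr + Sr.T)
    evals, evecs = np.linalg.eigh(Sr)
    lam_max = evals[-1] if len(evals) else 1.0
    tol = rtol * max(lam_max, 1.0)
    n_null = int(np.sum(evals < tol))
    if n_null != mono.n_holes:
        raise HarmonicKernelError(
            f"kernel dimension {n_null} != n_holes {mono.n_holes} "
            f"(tolerance {tol:.2e})"
        )
    weight = _mode_weight(mono, network)[re]
    modes: list[np.ndarray] = []
    if n_null:
        V = evecs[:, :n_null]
        # orthonormalize under the diagonal metric weight
        G = V.T @ (weight[:, None] * V)
        L = np.linalg.cholesky(G)
        V = V @ np.linalg.inv(L).T
        if n_null > 1:
            V = _localize_modes(mono, V, weight, re)
        for m in range(n_null):
            vec = V[:, m]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            full = np.zeros(mono.n_edges)
            full[re] = vec
            modes.append(full)
    return HarmonicBasis(network=network, modes=modes,
                         eigenvalues=evals[:max(n_null, min(4, len(evals)))],
                         null_tolerance=tol)


def _localize_modes(mono: Monolayer, V: np.ndarray, weight: np.ndarray,
                    re: np.ndarray) -> np.ndarray:
    """Rotate a multi-dimensional kernel basis so each mode attaches to
    one hole.

    Any rotation of the kernel is a valid eigenbasis; the physically
    natural one concentrates each mode's energy ``F_j (w_j/t_j)^2`` near
    a single hole.  For each hole (in turn) the kernel combination
    maximizing the energy fraction carried by the edges nearest that
    hole is extracted and deflated from the remaining subspace.
    """
    top = mono.topology
    g = mono.geometry
    centres = []
    for cycle in top.hole_boundaries:
        vs = np.unique(top.edge_vertices[cycle].ravel())
        centres.append(mono.r[vs].mean(axis=0))
    centres = np.asarray(centres)
    if len(centres) != V.shape[1]:
        return V
    d = np.linalg.norm(g.c[re, None, :] - centres[None], axis=2)
    nearest = np.argmin(d, axis=1)
    out = np.zeros_like(V)
    W = V.copy()
    for h in range(len(centres)):
        mask = (nearest == h).astype(float) * weight
        C = W.T @ (mask[:, None] * W)
        evals, evecs = np.linalg.eigh(C)
        x = evecs[:, -1]
        mode = W @ x
        mode /= np.sqrt(mode @ (weight * mode))
        out[:, h] = mode
        # deflate: M-orthogonal complement within the kernel
        coeff = W.T @ (weight * mode)
        W = W - np.outer(mode, coeff)
        # re-orthonormalize the remainder (rank n_null - h - 1)
        Gm = W.T @ (weight[:, None] * W)
        ev, U = np.linalg.eigh(Gm)
        keep = ev > 1e-12 * max(ev.max(), 1.0)
        W = (W @ U[:, keep]) / np.sqrt(ev[keep])
    return out


def harmonic_field(mono: Monolayer, basis: HarmonicBasis, m: int,
                   z_par: float, z_perp: float) -> EdgeVectorField:
    """Vector field of the m-th harmonic mode with amplitudes
    ``(z_par, z_perp)``; its squared norm is
    ``(z_par^2 + z_perp^2) sum_j F_j (w_j/t_j)^2``."""
    if not 0 <= m < basis.n_modes:
        raise IndexError(f"mode {m} out of range (n_modes={basis.n_modes})")
    w = Cochain("primal" if basis.network == "primal" else "dual",
                1, basis.modes[m], rank=0)
    return sharp(mono, interior_product((z_par, z_perp), w))


def harmonic_magnitude_profile(mono: Monolayer, basis: HarmonicBasis,
                               center: np.ndarray, m: int = 0) -> dict:
    """Per-edge scatter data for the harmonic magnitude around a hole.

    Returns distance of the edge centroid from ``center``, the magnitude
    ``chi_j = |w_j|/t_j`` and the orientation factor ``|cos theta_j)|``
    between the radial direction and the edge.
    """
    g = mono.geometry
    re = mono.metric.retained_edges
    w = basis.modes[m]
    d = g.c[re] - np.asarray(center, dtype=float)
    radius = np.linalg.norm(d, axis=1)
    chi = np.abs(w[re]) / g.t_len[re]
    with np.errstate(invalid="ignore"):
        cosang = np.abs(np.einsum("jd,jd->j", d, g.t[re])
                        / (radius * g.t_len[re]))
    return {"edge": re, "radius": radius, "chi": chi,
            "cos_theta": np.nan_to_num(cosang)}


@dataclass
class HodgeDecomposition:
    """Result of :func:`helmholtz_decompose`."""

    network: str
    phi: Cochain                     # pair potential, grad part
    u: Cochain                       # pair potential, rot part
    grad_part: EdgeVectorField
    rot_part: EdgeVectorField
    harmonic_part: EdgeVectorField | None
    amplitudes: np.ndarray           # (n_modes, 2) harmonic (z_par, z_perp)
    residual: EdgeVectorField        # v - grad - rot - harmonic(if any)
    diagnostics: dict = dataclass_field(default_factory=dict)


def _solve_dirichlet(K: sp.spmatrix, rhs: np.ndarray,
                     idx: np.ndarray, n: int) -> np.ndarray:
    """Solve the SPD system restricted to retained indices."""
    Kr = K[np.ix_(idx, idx)].tocsc()
    out = np.zeros((n, rhs.shape[1]))
    lu = spla.splu(Kr)
    for s in range(rhs.shape[1]):
        out[idx, s] = lu.solve(rhs[idx, s])
    return out


def _solve_singular(K: sp.spmatrix, rhs: np.ndarray,
                    areas: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the cell-centre Poisson problem with constant kernel.

    The forcing is projected onto the range (orthogonal complement of the
    constants), the system solved with one pinned entry, and the result
    gauged to zero area-weighted mean.  Returns the solution and the size
    of the applied projection.
    """
    n = K.shape[0]
    correction = float(np.abs(rhs.sum(axis=0)).max())
    rhs = rhs - rhs.mean(axis=0, keepdims=True)
    keep = np.arange(1, n)
    Kr = K[np.ix_(keep, keep)].tocsc()
    lu = spla.splu(Kr)
    out = np.zeros_like(rhs)
    for s in range(rhs.shape[1]):
        out[keep, s] = lu.solve(rhs[keep, s])
    out -= (areas @ out) / areas.sum()
    return out, correction


def helmholtz_decompose(mono: Monolayer, field: EdgeVectorField,
                        ops: OperatorSet | None = None,
                        basis: HarmonicBasis | None = None,
                        include_harmonic: bool = True) -> HodgeDecomposition:
    """Split an edge or link vector field into grad + rot + harmonic.

    With ``include_harmonic=False`` the harmonic projection is skipped and
    the remainder appears entirely in ``residual`` (the reconstruction
    defect used to detect excitation of harmonic fields).
    """
    if ops is None:
        ops = assemble_laplacians(mono, validate=False)
    network = "primal" if field.carrier == "edges" else "dual"
    met = mono.metric
    g = mono.geometry
    areas = g.A_cell
    diag: dict = {}

    f_div = neg_div(mono, field).values
    f_curl = curl(mono, field).values

    if network == "primal":
        rhs_phi = f_div * met.E_hat[:, None]
        phi_vals = _solve_dirichlet(ops.K_V, rhs_phi,
                                    met.retained_vertices, mono.n_vertices)
        phi = Cochain("primal", 0, phi_vals, rank=1)
        rhs_u = f_curl * areas[:, None]
        u_vals, corr = _solve_singular(ops.K_F, rhs_u, areas)
        u = Cochain("dual", 0, u_vals, rank=1)
        diag["solvability_correction_u"] = corr
    else:
        rhs_Phi = f_div * areas[:, None]
        Phi_vals, corr = _solve_singular(ops.K_C, rhs_Phi, areas)
        phi = Cochain("dual", 0, Phi_vals, rank=1)
        diag["solvability_correction_phi"] = corr
        rhs_U = f_curl * met.E_hat[:, None]
        U_vals = _solve_dirichlet(ops.K_T, rhs_U,
                                  met.retained_vertices, mono.n_vertices)
        u = Cochain("primal", 0, U_vals, rank=1)

    grad_part = grad(mono, phi)
    rot_part = rot(mono, u)

    harmonic_part = None
    amplitudes = np.zeros((0, 2))
    if include_harmonic and mono.n_holes > 0:
        if basis is None:
            basis = harmonic_basis(mono, ops, network=network)
        fb = flat(mono, field)
        weight = _mode_weight(mono, network)
        amplitudes = np.array([
            [float(np.sum(weight * w * fb.values[:, 0])),
             float(np.sum(weight * w * fb.values[:, 1]))]
            for w in basis.modes
        ])
        vec = np.zeros_like(field.vectors)
        for m, (zp, zq) in enumerate(amplitudes):
            vec += harmonic_field(mono, basis, m, zp, zq).vectors
        harmonic_part = EdgeVectorField(field.carrier, vec)

    res = field.vectors - grad_part.vectors - rot_part.vectors
    if harmonic_part is not None:
        res = res - harmonic_part.vectors
    re = met.retained_edges
    mask = np.zeros(mono.n_edges, dtype=bool)
    mask[re] = True
    res = np.where(mask[:, None], res, 0.0)
    residual = EdgeVectorField(field.carrier, res)
    diag["residual_max"] = float(np.abs(res).max(initial=0.0))
    diag["field_max"] = float(
        np.linalg.norm(field.vectors[re], axis=1).max(initial=0.0))
    return HodgeDecomposition(
        network=network, phi=phi, u=u,
        grad_part=grad_part, rot_part=rot_part,
        harmonic_part=harmonic_part, amplitudes=amplitudes,
        residual=residual, diagnostics=diag,
    )


def reconstruction_residual(mono: Monolayer, field: EdgeVectorField,
                            decomposition: HodgeDecomposition | None = None,
                            ops: OperatorSet | None = None) -> dict:
    """Defect ``x_breve = v - grad phi - rot u`` of a decomposition made
    without harmonic projection, with its norms.

    On a simply-connected equilibrated monolayer the defect is numerical
    noise; after ablation it reveals the excited harmonic component,
    radially oriented and concentrated at the hole.
    """
    if decomposition is None or decomposition.harmonic_part is not None:
        decomposition = helmholtz_decompose(mono, field, ops=ops,
                                            include_harmonic=False)
    res = decomposition.residual
    re = mono.metric.retained_edges
    norms = np.linalg.norm(res.vectors[re], axis=1)
    vmax = np.linalg.norm(field.vectors[re], axis=1).max(initial=0.0)
    return {
        "residual": res,
        "max_residual": float(norms.max(initial=0.0)),
        "max_field": float(vmax),
        "edge": re,
        "magnitude": norms,
    }
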