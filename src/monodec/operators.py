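"""Gradient, curl, divergence and rot on both networks, plus the six
Laplacians.

Each operator is one DEC composition; the (par, perp) slots of the
results are the named component operators of the decomposition machinery:

====================  =========================================
composition           slots (par, perp)
====================  =========================================
``grad  = (d phi)#``  grad / cograd (vectors along e_par/e_perp)
``curl  = (* d b_b)#``  (cocurl, curl) on cells or triangles
``-div  = * d * b_b``   (-div, -codiv) on vertices or centres
``rot   = (* d f_b)#``  corot / rot  (vectors along e_perp/e_par)
====================  =========================================

The scalar Laplacians assemble to ``L_V = E^-1 A^T Te^-1 A`` and cyclic
variants; the edge/link Laplacians ``L_E``, ``L_L`` act on scalar edge
(link) cochains and their kernels carry the harmonic fields.  All are
stored full-size with zero rows/columns at suppressed elements, together
with symmetrized forms used by the solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .dec import Cochain, EdgeVectorField, exterior_derivative, flat, sharp
from .monolayer import Monolayer

__all__ = [
    "OperatorSet",
    "grad",
    "curl",
    "neg_div",
    "div",
    "rot",
    "assemble_laplacians",
]


def _as_pair_cochain(mono: Monolayer, x, network: str, degree: int) -> Cochain:
    if isinstance(x, Cochain):
        return x
    return Cochain(network, degree, np.asarray(x, dtype=float), rank=1)


def grad(mono: Monolayer, phi) -> EdgeVectorField:
    """``(d phi)#`` for a pair-valued 0-cochain.

    On the primal network the par slot drives ``grad^v`` (vectors along
    ``e_par``) and the perp slot ``cograd^v``; mirrored with link bases on
    the dual network.
    """
    if isinstance(phi, Cochain):
        c = phi
    else:
        phi = np.asarray(phi, dtype=float)
        network = "primal" if len(phi) == mono.n_vertices else "dual"
        c = Cochain(network, 0, phi, rank=1)
    return sharp(mono, exterior_derivative(mono, c))


def curl(mono: Monolayer, field: EdgeVectorField) -> Cochain:
    """``(* d b_flat)#``: circulation-type derivatives.

    Edge fields map to cells with slots ``(cocurl^c, curl^c)`` where
    ``curl^c b = A_i^{-1} sum_j B_ij b_j . t_j``; link fields map to
    vertices with slots ``(cocurl^v, curl^v)``.
    """
    fb = flat(mono, field)
    d = exterior_derivative(mono, fb)
    # star_{1,2} = A^-1 eps_P (primal), star_{1,2}^dual = E^-1 eps_P
    from .dec import hodge_star

    return Cochain(**_star_12(mono, d))


def _star_12(mono: Monolayer, d: Cochain) -> dict:
    vals = np.stack([-d.values[:, 1], d.values[:, 0]], axis=1)
    if d.network == "primal":
        w = 1.0 / mono.geometry.A_cell
        return dict(network="dual", degree=0, values=vals * w[:, None], rank=1)
    met = mono.metric
    w = np.zeros(mono.n_vertices)
    rv = met.retained_vertices
    w[rv] = 1.0 / met.E_hat[rv]
    return dict(network="primal", degree=0, values=vals * w[:, None], rank=1)


def neg_div(mono: Monolayer, field: EdgeVectorField) -> Cochain:
    """``* d * b_flat`` — the adjoint of grad, i.e. ``-div b``.

    Edge fields give ``(-div^v, -codiv^v)`` on interior vertices; link
    fields give ``(-div^c, -codiv^c)`` on cell centres.  The composition
    reduces to a diagonal form: ``E^-1 A^T Te^-1`` applied to each flat
    component (primal), ``H^-1 B Tl^-1`` (dual).
    """
    fb = flat(mono, field)
    met = mono.metric
    red = mono.reduced
    if field.carrier == "edges":
        w = _safe_inv(met.T_e_hat)
        out = red.A_hat.T @ (fb.values * w[:, None])
        out *= _safe_inv(met.E_hat)[:, None]
        return Cochain("primal", 0, out, rank=1)
    w = _safe_inv(met.T_l_hat)
    out = red.B_hat @ (fb.values * w[:, None])
    out /= mono.geometry.A_cell[:, None]
    return Cochain("dual", 0, out, rank=1)


def div(mono: Monolayer, field: EdgeVectorField) -> Cochain:
    """Divergence-signed counterpart of :func:`neg_div`; the par slot
    recovers the continuum divergence of smooth fields."""
    c = neg_div(mono, field)
    return Cochain(c.network, c.degree, -c.values, rank=1)


def rot(mono: Monolayer, u) -> EdgeVectorField:
    """``(* d u_flat)#`` — adjoint of curl.

    For cell pairs the perp slot drives ``rot^c`` (vectors along
    ``e_par``), the par slot ``corot^c`` (along ``e_perp``); mirrored for
    vertex pairs with link bases.  Explicitly (primal):
    ``rot u = -(t_j^2/F_j) eps_P sum_i B_ij u_i`` projected on the edge
    bases.
    """
    if isinstance(u, Cochain):
        c = u
    else:
        u = np.asarray(u, dtype=float)
        network = "dual" if len(u) == mono.n_cells else "primal"
        c = Cochain(network, 0, u, rank=1)
    d = exterior_derivative(mono, c)  # pair-valued 1-cochain
    met = mono.metric
    if c.network == "dual":
        w = _safe_inv(met.T_e_hat, invert=False)  # t^2/F
        psi = -_rot_pair(d.values) * w[:, None]
        return sharp(mono, Cochain("primal", 1, psi, rank=1))
    w = _safe_inv(met.T_l_hat, invert=False)
    psi = -_rot_pair(d.values) * w[:, None]
    return sharp(mono, Cochain("dual", 1, psi, rank=1))


def _rot_pair(values: np.ndarray) -> np.ndarray:
    return np.stack([-values[:, 1], values[:, 0]], axis=1)


def _safe_inv(diag: np.ndarray, invert: bool = True) -> np.ndarray:
    out = np.zeros_like(diag)
    nz = diag != 0
    out[nz] = 1.0 / diag[nz] if invert else diag[nz]
    return out


@dataclass
class OperatorSet:
    """Assembled sparse Laplacians (full-size, zero at suppressed rows).

    ``L_V``/``L_C`` are the grad-adjoint Laplacians on interior vertices /
    cell centres, ``L_T``/``L_F`` the curl-adjoint ones, ``L_E``/``L_L``
    the edge/link Laplacians whose kernels hold one harmonic mode per
    hole.  ``S_E``/``S_L`` are the similarity-symmetrized forms
    (``L_E = T_e S_E`` etc.) used for eigen- and linear solves.
    """

    L_V: sp.csr_matrix
    L_C: sp.csr_matrix
    L_T: sp.csr_matrix
    L_F: sp.csr_matrix
    L_E: sp.csr_matrix
    L_L: sp.csr_matrix
    S_E: sp.csr_matrix
    S_L: sp.csr_matrix
    K_V: sp.csr_matrix   # A^T Te^-1 A   (= E_hat L_V)
    K_C: sp.csr_matrix   # B Tl^-1 B^T   (= H L_C)
    K_T: sp.csr_matrix   # A^T Tl A      (= E_hat L_T)
    K_F: sp.csr_matrix   # B Te B^T      (= H L_F)


def assemble_laplacians(mono: Monolayer, validate: bool = True) -> OperatorSet:
    """Build all Laplacians from the reduced incidence and metric weights.

    With ``validate`` a cheap random-vector check confirms the operator
    compositions (``-div grad = L_V``, ``curl rot = L_F`` and the dual
    pair) against the assembled matrices.
    """
    met = mono.metric
    red = mono.reduced
    A_hat = red.A_hat.astype(float)
    B_hat = red.B_hat.astype(float)
    Einv = sp.diags(_safe_inv(met.E_hat))
    Hinv = sp.diags(1.0 / mono.geometry.A_cell)
    Te = sp.diags(met.T_e_hat)
    Tl = sp.diags(met.T_l_hat)
    Teinv = sp.diags(_safe_inv(met.T_e_hat))
    Tlinv = sp.diags(_safe_inv(met.T_l_hat))

    L_V = (Einv @ A_hat.T @ Teinv @ A_hat).tocsr()
    L_C = (Hinv @ B_hat @ Tlinv @ B_hat.T).tocsr()
    L_T = (Einv @ A_hat.T @ Tl @ A_hat).tocsr()
    L_F = (Hinv @ B_hat @ Te @ B_hat.T).tocsr()
    L_E = (A_hat @ Einv @ A_hat.T @ Teinv + Te @ B_hat.T @ Hinv @ B_hat).tocsr()
    L_L = (B_hat.T @ Hinv @ B_hat @ Tlinv + Tl @ A_hat @ Einv @ A_hat.T).tocsr()
    S_E = (Teinv @ A_hat @ Einv @ A_hat.T @ Teinv + B_hat.T @ Hinv @ B_hat).tocsr()
    S_L = (Tlinv @ B_hat.T @ Hinv @ B_hat @ Tlinv + A_hat @ Einv @ A_hat.T).tocsr()
    K_V = (A_hat.T @ Teinv @ A_hat).tocsr()
    K_C = (B_hat @ Tlinv @ B_hat.T).tocsr()
    K_T = (A_hat.T @ Tl @ A_hat).tocsr()
    K_F = (B_hat @ Te @ B_hat.T).tocsr()

    ops = OperatorSet(L_V=L_V, L_C=L_C, L_T=L_T, L_F=L_F, L_E=L_E, L_L=L_L,
                      S_E=S_E, S_L=S_L, K_V=K_V, K_C=K_C, K_T=K_T, K_F=K_F)
    if validate:
        _validate_compositions(mono, ops)
    return ops


def _validate_compositions(mono: Monolayer, ops: OperatorSet,
                           tol: float = 1e-9) -> None:
    rng = np.random.default_rng(0)
    rv = mono.metric.retained_vertices
    phi = np.zeros((mono.n_vertices, 2))
    phi[rv] = rng.normal(size=(len(rv), 2))
    lhs = neg_div(mono, grad(mono, phi)).values
    rhs = ops.L_V @ phi
    scale = max(abs(rhs).max(), 1.0)
    if abs(lhs - rhs).max() > tol * scale:
        raise AssertionError("composition -div grad != L_V")
    u = rng.normal(size=(mono.n_cells, 2))
    lhs = curl(mono, rot(mono, u)).values
    rhs = ops.L_F @ u
    if abs(lhs - rhs).max() > tol * max(abs(rhs).max(), 1.0):
        raise AssertionError("composition curl rot != L_F")
    Phi = rng.normal(size=(mono.n_cells, 2))
    lhs = neg_div(mono, grad(mono, Cochain("dual", 0, Phi, 1))).values
    rhs = ops.L_C @ Phi
    if abs(lhs - rhs).max() > tol * max(abs(rhs).max(), 1.0):
        raise AssertionError("composition -div grad != L_C (dual)")
    U = np.zeros((mono.n_vertices, 2))
    U[rv] = rng.normal(size=(len(rv), 2))
    lhs = curl(mono, rot(mono, Cochain("primal", 0, U, 1))).values
    rhs = ops.L_T @ U
    if abs(lhs - rhs).max() > tol * max(abs(rhs).max(), 1.0):
        raise AssertionError("composition curl rot != L_T (dual)")
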