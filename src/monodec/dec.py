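"""Discrete-exterior-calculus primitives on the reduced networks.

Cochains carry either scalar values or component pairs ``(par, perp)``
projected onto bases aligned with cell edges (primal) or links (dual):

* contravariant: ``e_par = t/t^2``, ``e_perp = eps_i t / t^2``
* covariant:     ``e^par = t``,     ``e^perp = eps_i t``

and the analogues with the link vector ``T`` and the opposite rotation
``eps_k = -eps_i``.  Sharp projects component pairs onto the contravariant
basis; flat contracts vectors with the covariant one, so the two are exact
inverses.  The exterior derivative is the coboundary (reduced incidence
matrix) applied componentwise; Hodge stars are diagonal area/length
weights, with an extra quarter rotation ``eps_P = [[0,-1],[1,0]]`` acting
on the component pair of pair-valued cochains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .monolayer import Monolayer

__all__ = [
    "EPS_P",
    "Cochain",
    "EdgeVectorField",
    "basis_vectors",
    "exterior_derivative",
    "sharp",
    "flat",
    "hodge_star",
    "hodge_star_inverse",
    "wedge_value",
    "wedge_scalar",
    "wedge_tilde",
    "interior_product",
    "inner_product",
]

#: rotation acting on the (par, perp) value pair of pair-valued cochains
EPS_P = np.array([[0.0, -1.0], [1.0, 0.0]])


def _rot_pair(values: np.ndarray) -> np.ndarray:
    """Apply eps_P to each (par, perp) pair."""
    return np.stack([-values[:, 1], values[:, 0]], axis=1)


@dataclass
class Cochain:
    """Field over vertices/edges/cells of the primal or dual network.

    ``values`` has shape (n,) for scalar-valued cochains and (n, 2) for
    pair-valued ones, ordered (par, perp).  ``rank`` is the value-leg
    degree (0 and 2 are stored as scalars in 2D).  Arrays are full-length;
    suppressed (peripheral) entries are kept at zero.
    """

    network: str          # "primal" | "dual"
    degree: int           # 0, 1, 2 (chain leg)
    values: np.ndarray
    rank: int = 0         # 0, 1, 2 (value leg)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        want = 2 if self.rank == 1 else 1
        if self.values.ndim != want:
            raise ValueError(
                f"rank-{self.rank} cochain needs {want}-d values, "
                f"got shape {self.values.shape}"
            )

    def copy(self) -> "Cochain":
        return Cochain(self.network, self.degree, self.values.copy(), self.rank)


@dataclass
class EdgeVectorField:
    """One 2D vector per edge (carrier 'edges') or per link ('links')."""

    carrier: str
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.carrier not in ("edges", "links"):
            raise ValueError(f"unknown carrier {self.carrier!r}")

    def copy(self) -> "EdgeVectorField":
        return EdgeVectorField(self.carrier, self.vectors.copy())


def _check_length(mono: Monolayer, cochain: Cochain) -> None:
    n = mono.carrier_size(cochain.network, cochain.degree)
    if len(cochain.values) != n:
        raise ValueError(
            f"cochain on {cochain.network} degree {cochain.degree}: "
            f"{len(cochain.values)} values, carrier has {n}"
        )


def basis_vectors(mono: Monolayer, carrier: str) -> dict[str, np.ndarray]:
    """Contravariant/covariant bases per edge (or link), zero on suppressed
    elements of the reduced network."""
    from .mesh import EPS_I, EPS_K

    g = mono.geometry
    if carrier == "edges":
        up_par, eps = g.t, EPS_I
        length2 = g.t_len ** 2
    elif carrier == "links":
        up_par, eps = g.T, EPS_K
        length2 = g.T_len ** 2
    else:
        raise ValueError(f"unknown carrier {carrier!r}")
    up_perp = up_par @ eps.T
    return {
        "e_par": up_par / length2[:, None],
        "e_perp": up_perp / length2[:, None],
        "e_up_par": up_par,
        "e_up_perp": up_perp,
    }


def exterior_derivative(mono: Monolayer, cochain: Cochain) -> Cochain:
    """Reduced coboundary, applied to each value component; ``d(d x) = 0``."""
    _check_length(mono, cochain)
    red = mono.reduced
    if cochain.degree == 0:
        op = red.A_hat if cochain.network == "primal" else red.B_hat.T
    elif cochain.degree == 1:
        op = red.B_hat if cochain.network == "primal" else red.A_hat.T
    else:
        raise ValueError("exterior derivative undefined for degree-2 cochains")
    return Cochain(cochain.network, cochain.degree + 1,
                   op @ cochain.values, cochain.rank)


def sharp(mono: Monolayer, cochain: Cochain):
    """Musical isomorphism to vectors (degree 1) or chains (degree 0).

    For pair-valued 1-cochains returns the vector field
    ``psi_par e_par + psi_perp e_perp``; for degree 0 the map is a pure
    basis relabelling and the component pair is returned unchanged.
    """
    if cochain.rank != 1:
        raise ValueError("sharp acts on pair-valued cochains")
    if cochain.degree == 0:
        return cochain.values.copy()
    if cochain.degree != 1:
        raise ValueError("sharp defined for degrees 0 and 1")
    carrier = "edges" if cochain.network == "primal" else "links"
    bas = basis_vectors(mono, carrier)
    vec = (cochain.values[:, :1] * bas["e_par"]
           + cochain.values[:, 1:] * bas["e_perp"])
    return EdgeVectorField(carrier, vec)


def flat(mono: Monolayer, field: EdgeVectorField) -> Cochain:
    """Contraction with the covariant basis: components
    ``(v . e^par, v . e^perp)`` per edge or link."""
    bas = basis_vectors(mono, field.carrier)
    vals = np.stack([
        np.einsum("jd,jd->j", field.vectors, bas["e_up_par"]),
        np.einsum("jd,jd->j", field.vectors, bas["e_up_perp"]),
    ], axis=1)
    network = "primal" if field.carrier == "edges" else "dual"
    return Cochain(network, 1, vals, rank=1)


def _star_scale(mono: Monolayer, network: str, degree: int) -> np.ndarray:
    """Diagonal weight of the Hodge star for a cochain on (network, degree).

    Suppressed elements carry weight zero (hence the hats); the degree-2
    stars divide by the area weights instead.
    """
    g, met = mono.geometry, mono.metric
    re = met.retained_edges
    if network == "primal":
        if degree == 0:
            return met.E_hat
        if degree == 1:
            w = np.zeros(mono.n_edges)
            w[re] = g.F[re] / g.t_len[re] ** 2
            return w
        return 1.0 / g.A_cell
    else:
        if degree == 0:
            return g.A_cell.copy()
        if degree == 1:
            w = np.zeros(mono.n_edges)
            w[re] = g.F[re] / g.T_len[re] ** 2
            return w
        w = np.zeros(mono.n_vertices)
        rv = met.retained_vertices
        w[rv] = 1.0 / met.E_hat[rv]
        return w


def hodge_star(mono: Monolayer, cochain: Cochain) -> Cochain:
    """Hodge star onto the opposite network.

    Scalar-valued cochains are scaled by the diagonal weight; pair-valued
    ones additionally rotate by ``eps_P``.  Star pairs satisfy the inverse
    relations ``star_{1,0}^{-1} = -star_{1,2}^dual`` and cyclic variants.
    """
    _check_length(mono, cochain)
    w = _star_scale(mono, cochain.network, cochain.degree)
    vals = cochain.values
    if cochain.rank == 1:
        vals = _rot_pair(vals) * w[:, None]
    else:
        vals = vals * w
    other = "dual" if cochain.network == "primal" else "primal"
    return Cochain(other, 2 - cochain.degree, vals, 2 - cochain.rank)


def hodge_star_inverse(mono: Monolayer, cochain: Cochain) -> Cochain:
    """Inverse of the star that produced ``cochain`` (suppressed entries
    stay zero)."""
    _check_length(mono, cochain)
    other = "dual" if cochain.network == "primal" else "primal"
    w = _star_scale(mono, other, 2 - cochain.degree)
    winv = np.zeros_like(w)
    nz = w != 0
    winv[nz] = 1.0 / w[nz]
    vals = cochain.values
    if cochain.rank == 1:
        vals = -_rot_pair(vals) * winv[:, None]   # eps_P^{-1} = -eps_P
    else:
        vals = vals * winv
    return Cochain(other, 2 - cochain.degree, vals, 2 - cochain.rank)


def wedge_value(mono: Monolayer, a, b) -> Cochain:
    """Value-leg wedge of two vector fields on the same carrier:
    ``sum_j (a_par b_perp - a_perp b_par) q_j``; antisymmetric."""
    fa = flat(mono, a) if isinstance(a, EdgeVectorField) else a
    fb = flat(mono, b) if isinstance(b, EdgeVectorField) else b
    if fa.network != fb.network or fa.degree != fb.degree:
        raise ValueError("wedge requires matching carrier and network")
    if fa.rank != 1 or fb.rank != 1:
        raise ValueError("use wedge_scalar for the scalar-by-pair wedge")
    av, bv = fa.values, fb.values
    out = av[:, 0] * bv[:, 1] - av[:, 1] * bv[:, 0]
    return Cochain(fa.network, fa.degree, out, rank=2)


def wedge_scalar(mono: Monolayer, phi: Cochain, v) -> Cochain:
    """Graded-commutative wedge of a scalar 1-cochain with a vector field:
    ``phi_j {v_perp, -v_par}`` per element."""
    fv = flat(mono, v) if isinstance(v, EdgeVectorField) else v
    if phi.rank != 0:
        raise ValueError("first argument must be scalar-valued")
    vals = phi.values[:, None] * np.stack(
        [fv.values[:, 1], -fv.values[:, 0]], axis=1)
    return Cochain(fv.network, fv.degree, vals, rank=1)


def wedge_tilde(mono: Monolayer, a: Cochain, b: Cochain) -> Cochain:
    """Chain-leg wedge of two scalar 1-cochains (quadruple incidence sum).

    For link cochains the result lives on triangles (dual 2-cochains);
    for edge cochains on cells.  Contracted through cell/vertex pairings:
    ``(a ~^ b)_k = sum_{i,j,j'} A_jk B_ij' |A_j'k| |B_ij| a_j b_j'``.
    """
    if a.rank != 0 or b.rank != 0 or a.degree != 1 or b.degree != 1:
        raise ValueError("wedge_tilde takes scalar 1-cochains")
    if a.network != b.network:
        raise ValueError("operands must live on the same network")
    import scipy.sparse as sp

    A, B = mono.topology.A, mono.topology.B
    absA, absB = abs(A), abs(B)
    Da, Db = sp.diags(a.values), sp.diags(b.values)
    if a.network == "dual":   # link cochains -> vertices
        P = absB @ Da @ A          # (i,k)
        Q = B @ Db @ absA          # (i,k)
        out = np.asarray(P.multiply(Q).sum(axis=0)).ravel()
        return Cochain("dual", 2, out, rank=0)
    P = B @ Da @ absA              # (i,k)
    Q = absB @ Db @ A              # (i,k)
    out = np.asarray(P.multiply(Q).sum(axis=1)).ravel()
    return Cochain("primal", 2, out, rank=0)


def interior_product(z: np.ndarray, w: Cochain) -> Cochain:
    """Contraction of a scalar 1-cochain with a uniform component pair
    ``z = (z_par, z_perp)``: components ``(z_par w_j, z_perp w_j)``."""
    if w.rank != 0 or w.degree != 1:
        raise ValueError("interior_product expects a scalar 1-cochain")
    z = np.asarray(z, dtype=float)
    vals = np.stack([z[0] * w.values, z[1] * w.values], axis=1)
    return Cochain(w.network, 1, vals, rank=1)


def inner_product(mono: Monolayer, x, y) -> float:
    """Metric inner products of the reduced networks.

    Vector fields on edges/links pair with weight ``F_j``; component pairs
    on vertices pair with ``E_k`` (interior only) and on cells with
    ``A_i``.
    """
    met = mono.metric
    if isinstance(x, EdgeVectorField) and isinstance(y, EdgeVectorField):
        if x.carrier != y.carrier:
            raise ValueError("carrier mismatch")
        re = met.retained_edges
        F = mono.geometry.F
        return float(np.einsum("j,jd,jd->", F[re], x.vectors[re], y.vectors[re]))
    if isinstance(x, Cochain) and isinstance(y, Cochain):
        if x.network != y.network or x.degree != y.degree or x.rank != y.rank:
            raise ValueError("carrier mismatch")
        if x.degree != 0 or x.rank != 1:
            raise ValueError("inner product defined for pair-valued 0-cochains")
        if x.network == "primal":
            w = met.E_hat
        else:
            w = mono.geometry.A_cell
        return float(np.einsum("k,kd,kd->", w, x.values, y.values))
    # pair-valued chains represented as raw (n,2) arrays on vertices/cells
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("carrier mismatch")
    if x.shape[0] == mono.n_vertices:
        w = met.E_hat
    elif x.shape[0] == mono.n_cells:
        w = mono.geometry.A_cell
    else:
        raise ValueError("unrecognized carrier length")
    return float(np.einsum("k,kd,kd->", w, x, y))
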