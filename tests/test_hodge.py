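"""Harmonic fields and the Helmholtz-Hodge decomposition."""

import numpy as np
import pytest

import monodec as md
from monodec.dec import Cochain
from monodec.hodge import HarmonicKernelError

from conftest import random_edge_field

RNG = np.random.default_rng(13)


class TestHarmonicBasis:
    def test_kernel_dimension_matches_holes(self, hex3, annulus1, annulus2):
        assert md.harmonic_basis(hex3).n_modes == 0
        assert md.harmonic_basis(annulus1).n_modes == 1
        assert md.harmonic_basis(annulus2).n_modes == 2

    def test_three_hole_fixture(self):
        top, r = md.fixture_hexagonal_patch(4)
        cells = top.cells
        centres = np.array([r[c].mean(axis=0) for c in cells])
        # remove three far-apart interior cells
        targets = [np.array([0.0, 0.0]), np.array([2 * np.sqrt(3), 0.0]),
                   np.array([-2 * np.sqrt(3), 0.0])]
        drop = {int(np.argmin(np.linalg.norm(centres - t, axis=1)))
                for t in targets}
        kept = [c for i, c in enumerate(cells) if i not in drop]
        used = sorted({v for c in kept for v in c})
        remap = {v: i for i, v in enumerate(used)}
        mono = md.Monolayer([[remap[v] for v in c] for c in kept], r[used])
        assert mono.n_holes == 3
        assert md.harmonic_basis(mono).n_modes == 3

    def test_modes_divergence_and_curl_free(self, annulus1, annulus2):
        for mono in (annulus1, annulus2):
            basis = md.harmonic_basis(mono)
            for m in range(basis.n_modes):
                x = md.harmonic_field(mono, basis, m, 1.0, 0.5)
                assert abs(md.neg_div(mono, x).values).max() < 1e-8
                assert abs(md.curl(mono, x).values).max() < 1e-8

    def test_norm_identity(self, annulus1):
        basis = md.harmonic_basis(annulus1)
        g = annulus1.geometry
        re = annulus1.metric.retained_edges
        for zp, zq in [(1.0, 0.0), (0.4, -2.0)]:
            x = md.harmonic_field(annulus1, basis, 0, zp, zq)
            expect = (zp ** 2 + zq ** 2) * np.sum(
                g.F[re] * (basis.modes[0][re] / g.t_len[re]) ** 2)
            assert md.inner_product(annulus1, x, x) == pytest.approx(
                expect, rel=1e-10)

    def test_zero_amplitudes(self, annulus1):
        basis = md.harmonic_basis(annulus1)
        x = md.harmonic_field(annulus1, basis, 0, 0.0, 0.0)
        assert abs(x.vectors).max() == 0.0

    def test_mode_index_out_of_range(self, annulus1):
        basis = md.harmonic_basis(annulus1)
        with pytest.raises(IndexError):
            md.harmonic_field(annulus1, basis, 5, 1.0, 0.0)

    def test_two_hole_modes_localized(self, annulus2):
        """Each mode concentrates its energy near one hole."""
        mono = annulus2
        basis = md.harmonic_basis(mono)
        g = mono.geometry
        top = mono.topology
        hole_centres = []
        for cycle in top.hole_boundaries:
            vs = np.unique(top.edge_vertices[cycle].ravel())
            hole_centres.append(mono.r[vs].mean(axis=0))
        hole_centres = np.asarray(hole_centres)
        re = mono.metric.retained_edges
        weights = g.F[re] / g.t_len[re] ** 2
        assignments = []
        for m in range(2):
            w2 = weights * basis.modes[m][re] ** 2
            d = np.linalg.norm(g.c[re, None, :] - hole_centres[None], axis=2)
            nearest = np.argmin(d, axis=1)
            share = [w2[nearest == h].sum() for h in range(2)]
            assignments.append(int(np.argmax(share)))
            assert max(share) > 0.7 * sum(share)
        assert set(assignments) == {0, 1}

    def test_dual_mode_matches_primal_up_to_scale_orthogonal(self, annulus1):
        """On the orthogonal fixture the link-network harmonic mode is the
        edge-network mode (up to normalization)."""
        bp = md.harmonic_basis(annulus1, network="primal")
        bd = md.harmonic_basis(annulus1, network="dual")
        re = annulus1.metric.retained_edges
        wp, wd = bp.modes[0][re], bd.modes[0][re]
        ratio = wd[np.abs(wp) > 1e-8] / wp[np.abs(wp) > 1e-8]
        assert np.allclose(ratio, ratio[0], atol=1e-8)

    def test_kernel_mismatch_raises(self, annulus1):
        ops = md.assemble_laplacians(annulus1, validate=False)
        with pytest.raises(HarmonicKernelError):
            md.harmonic_basis(annulus1, ops, rtol=1e2)  # everything "null"


class TestMagnitudeProfile:
    def test_profile_nonnegative_and_radial_dominance(self, annulus1):
        mono = annulus1
        basis = md.harmonic_basis(mono)
        top = mono.topology
        vs = np.unique(top.edge_vertices[top.hole_boundaries[0]].ravel())
        center = mono.r[vs].mean(axis=0)
        prof = md.harmonic_magnitude_profile(mono, basis, center)
        assert np.all(prof["chi"] >= 0)
        assert np.all(prof["cos_theta"] <= 1 + 1e-12)
        # radially oriented edges dominate the upper envelope
        big = prof["chi"] > np.quantile(prof["chi"], 0.9)
        assert prof["cos_theta"][big].mean() > prof["cos_theta"].mean()


class TestDecomposition:
    def test_grad_only_recovery(self, annulus1):
        mono = annulus1
        ops = md.assemble_laplacians(mono, validate=False)
        rv = mono.metric.retained_vertices
        phi0 = np.zeros((mono.n_vertices, 2))
        phi0[rv] = RNG.normal(size=(len(rv), 2))
        v = md.grad(mono, phi0)
        dec = md.helmholtz_decompose(mono, v, ops)
        re = mono.metric.retained_edges
        scale = np.linalg.norm(v.vectors[re], axis=1).max()
        assert np.linalg.norm(dec.residual.vectors[re], axis=1).max() < 1e-6 * scale
        assert abs(dec.phi.values - phi0).max() < 1e-8
        assert abs(dec.u.values).max() < 1e-8
        assert abs(dec.amplitudes).max() < 1e-8

    def test_rot_only_recovery(self, annulus1):
        mono = annulus1
        ops = md.assemble_laplacians(mono, validate=False)
        u0 = RNG.normal(size=(mono.n_cells, 2))
        v = md.rot(mono, u0)
        dec = md.helmholtz_decompose(mono, v, ops)
        re = mono.metric.retained_edges
        scale = np.linalg.norm(v.vectors[re], axis=1).max()
        assert np.linalg.norm(dec.residual.vectors[re], axis=1).max() < 1e-6 * scale
        assert abs(dec.phi.values).max() < 1e-8
        # u recovered up to the area-weighted-mean gauge
        A = mono.geometry.A_cell
        u0g = u0 - (A @ u0) / A.sum()
        assert abs(dec.u.values - u0g).max() < 1e-8

    def test_mixed_recovery_with_harmonic(self, annulus1):
        mono = annulus1
        ops = md.assemble_laplacians(mono, validate=False)
        basis = md.harmonic_basis(mono, ops)
        rv = mono.metric.retained_vertices
        phi0 = np.zeros((mono.n_vertices, 2))
        phi0[rv] = RNG.normal(size=(len(rv), 2))
        u0 = RNG.normal(size=(mono.n_cells, 2))
        z = (0.7, -0.3)
        v = md.EdgeVectorField("edges",
                               md.grad(mono, phi0).vectors
                               + md.rot(mono, u0).vectors
                               + md.harmonic_field(mono, basis, 0, *z).vectors)
        dec = md.helmholtz_decompose(mono, v, ops, basis=basis)
        assert dec.amplitudes[0] == pytest.approx(z, abs=1e-9)
        re = mono.metric.retained_edges
        scale = np.linalg.norm(v.vectors[re], axis=1).max()
        assert np.linalg.norm(dec.residual.vectors[re], axis=1).max() < 1e-6 * scale

    def test_orthogonality_of_components(self, annulus1):
        mono = annulus1
        v = random_edge_field(mono, RNG)
        dec = md.helmholtz_decompose(mono, v)
        gg = md.inner_product(mono, dec.grad_part, dec.grad_part)
        rr = md.inner_product(mono, dec.rot_part, dec.rot_part)
        hh = md.inner_product(mono, dec.harmonic_part, dec.harmonic_part)
        for x, y in [(dec.grad_part, dec.rot_part),
                     (dec.grad_part, dec.harmonic_part),
                     (dec.rot_part, dec.harmonic_part)]:
            ip = md.inner_product(mono, x, y)
            assert abs(ip) < 1e-8 * max(gg, rr, hh, 1.0)

    def test_harmonic_input_fully_captured(self, annulus1):
        mono = annulus1
        basis = md.harmonic_basis(mono)
        x = md.harmonic_field(mono, basis, 0, 1.0, 0.0)
        dec = md.helmholtz_decompose(mono, x, basis=basis)
        energy = md.inner_product(mono, x, x)
        captured = md.inner_product(mono, dec.harmonic_part, dec.harmonic_part)
        assert captured >= 0.99 * energy
        assert abs(dec.phi.values).max() < 1e-8
        assert abs(dec.u.values).max() < 1e-8

    def test_dual_decomposition_recovery(self, annulus1):
        mono = annulus1
        Phi0 = RNG.normal(size=(mono.n_cells, 2))
        V = md.grad(mono, Cochain("dual", 0, Phi0, 1))
        dec = md.helmholtz_decompose(mono, V)
        re = mono.metric.retained_edges
        scale = np.linalg.norm(V.vectors[re], axis=1).max()
        assert np.linalg.norm(dec.residual.vectors[re], axis=1).max() < 1e-6 * scale
        # recovered up to constant gauge
        d = dec.phi.values - Phi0
        assert abs(d - d.mean(axis=0)).max() < 1e-8

    def test_orthogonal_fixture_potential_identifications(self, annulus1):
        """On the orthogonal lattice the primal and dual decompositions
        identify: phi_par = -U_par and phi_perp = U_perp."""
        mono = annulus1
        rv = mono.metric.retained_vertices
        phi0 = np.zeros((mono.n_vertices, 2))
        phi0[rv] = RNG.normal(size=(len(rv), 2))
        u0 = RNG.normal(size=(mono.n_cells, 2))
        vec = (md.grad(mono, phi0).vectors + md.rot(mono, u0).vectors)
        dec_p = md.helmholtz_decompose(mono, md.EdgeVectorField("edges", vec))
        dec_d = md.helmholtz_decompose(mono, md.EdgeVectorField("links", vec))
        U = dec_d.u.values   # pair potential on vertices (dual network)
        phi = dec_p.phi.values
        assert abs(phi[:, 0] + U[:, 0]).max() < 1e-8
        assert abs(phi[:, 1] - U[:, 1]).max() < 1e-8

    def test_reconstruction_residual_synthetic_exact(self, hex3):
        mono = hex3
        rv = mono.metric.retained_vertices
        phi0 = np.zeros((mono.n_vertices, 2))
        phi0[rv] = RNG.normal(size=(len(rv), 2))
        u0 = RNG.normal(size=(mono.n_cells, 2))
        v = md.EdgeVectorField("edges", md.grad(mono, phi0).vectors
                               + md.rot(mono, u0).vectors)
        rep = md.reconstruction_residual(mono, v)
        assert rep["max_residual"] < 1e-10 * max(rep["max_field"], 1.0)
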