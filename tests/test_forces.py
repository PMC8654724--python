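"""Force-law tests: scalar laws, center velocities, vertex forces, matchings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import tissuemech as tm
from tissuemech.forces import g_exp_prime, g_poly_prime
from tissuemech.microsim import CellGeometry

from conftest import random_centers_2d


class TestExpForce:
    def test_zero_at_rest_and_beyond_cutoff(self, exp_force):
        assert tm.g_exp(1.0, exp_force) == 0.0
        assert tm.g_exp(1.6, exp_force) == 0.0

    def test_adhesion_value(self, exp_force):
        # mu (r-s) exp(-c (r-s)) at r=1.2: 50*0.2*e^-2 = 10 e^-2
        assert tm.g_exp(1.2, exp_force) == pytest.approx(10.0 * math.exp(-2.0), rel=1e-12)

    def test_sign_pattern(self, exp_force):
        r = np.linspace(1e-6, 3.0, 2000)
        g = tm.g_exp(r, exp_force)
        assert np.all(g[r < exp_force.s] < 0)
        assert np.all(g[(r > exp_force.s) & (r < exp_force.r_A)] > 0)
        assert np.all(g[r > exp_force.r_A] == 0)

    def test_negative_distance_rejected(self, exp_force):
        with pytest.raises(ValueError):
            tm.g_exp(-0.1, exp_force)

    def test_derivative_matches_finite_difference(self, exp_force):
        r = np.linspace(0.1, 1.4, 27)
        h = 1e-7
        fd = (tm.g_exp(r + h, exp_force) - tm.g_exp(r - h, exp_force)) / (2 * h)
        np.testing.assert_allclose(g_exp_prime(r, exp_force), fd, rtol=1e-6, atol=1e-8)


class TestPolyForce:
    def test_zero_at_cutoff_and_continuity(self, poly_force):
        assert tm.g_poly(poly_force.r_A, poly_force) == pytest.approx(0.0, abs=1e-15)
        eps = 1e-9
        below = tm.g_poly(poly_force.r_R - eps, poly_force)
        above = tm.g_poly(poly_force.r_R + eps, poly_force)
        assert below == pytest.approx(above, abs=1e-7)

    def test_zero_distance_formula_matches_root(self, poly_force):
        s = tm.poly_zero_distance(poly_force)
        root = brentq(lambda r: tm.g_poly(r, poly_force), 0.2, poly_force.r_R)
        assert s == pytest.approx(root, abs=1e-10)
        assert s == pytest.approx(0.5541, abs=2e-4)
        assert tm.g_poly(s, poly_force) == pytest.approx(0.0, abs=1e-10)

    def test_no_adhesion_zero_at_repulsion_edge(self):
        p = tm.PolyForceParams(c_r=2.0, c_a=0.0, r_R=1.0, r_A=1.5, n=1)
        assert p.s == p.r_R

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            tm.PolyForceParams(c_r=1.0, c_a=1.0, r_R=1.0, r_A=1.5, n=1)

    def test_sign_pattern(self, poly_force):
        s = tm.poly_zero_distance(poly_force)
        r = np.linspace(1e-6, 3.0, 2000)
        g = tm.g_poly(r, poly_force)
        assert np.all(g[r < s - 1e-9] < 0)
        assert np.all(g[(r > s + 1e-9) & (r < poly_force.r_A)] > 0)
        assert np.all(g[r > poly_force.r_A] == 0)

    def test_derivative_matches_finite_difference(self, poly_force):
        r = np.linspace(0.1, 1.45, 23)
        h = 1e-7
        fd = (tm.g_poly(r + h, poly_force) - tm.g_poly(r - h, poly_force)) / (2 * h)
        np.testing.assert_allclose(g_poly_prime(r, poly_force), fd, rtol=1e-5, atol=1e-8)


class TestCBMVelocities:
    def test_pair_at_rest_distance(self, exp_force):
        v = tm.cbm_velocities(tm.CellCenters([0.0, 1.0]), exp_force)
        np.testing.assert_allclose(v, 0.0, atol=1e-15)

    def test_symmetric_triple(self, exp_force):
        v = tm.cbm_velocities(tm.CellCenters([0.0, 1.2, 2.4]), exp_force)
        assert v[1, 0] == pytest.approx(0.0, abs=1e-14)

    def test_asymmetric_triple(self, exp_force):
        # middle cell: g(1.1) - g(1.2) = 5 e^-1 - 10 e^-2
        v = tm.cbm_velocities(tm.CellCenters([0.0, 1.2, 2.3]), exp_force)
        expected = 5.0 * math.exp(-1.0) - 10.0 * math.exp(-2.0)
        assert v[1, 0] == pytest.approx(expected, rel=1e-12)

    def test_coincident_rejected(self, exp_force):
        with pytest.raises(ValueError, match="coincident"):
            tm.cbm_velocities(tm.CellCenters([[0.0, 0.0], [0.0, 0.0]]), exp_force)

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=50)
    def test_momentum_conservation(self, exp_force, seed):
        """Pair antisymmetry implies sum_i v_i = 0 componentwise."""
        rng = np.random.default_rng(seed)
        dom = tm.Domain((0.0, 0.0), (6.0, 6.0))
        centers = random_centers_2d(rng, 20, dom)
        v = tm.cbm_velocities(centers, exp_force)
        # tolerance scaled by the largest speed (close pairs give huge forces)
        np.testing.assert_allclose(
            v.sum(axis=0), 0.0, atol=1e-10 * max(1.0, float(np.abs(v).max()))
        )


class TestVertexForces:
    def test_wo_force_function_values(self):
        p = tm.WOParams(sigma=1.0, kappa=1.0)
        assert tm.wo_force_function(2.0, 0.0, 0.0, tm.WOParams(sigma=1.0, kappa=0.0)) == 0.5
        a = 3.7223
        assert tm.wo_force_function(1.0, a, a, p) == pytest.approx(1.0 + 2 * a)

    def test_uniform_lattice_equilibrium(self, hex_sheet, deep_interior_vertices):
        """Three edges at 120 degrees with equal weights sum to zero."""
        _, _, tess, mesh = hex_sheet
        p = tm.WOParams(sigma=1.0, kappa=1.0)
        for a in deep_interior_vertices:
            v = tm.wo_vertex_velocity(a, mesh, tess, p)
            np.testing.assert_allclose(v, 0.0, atol=1e-10)

    def test_scaled_lattice_symmetry(self, hex_sheet, deep_interior_vertices):
        """Uniformly scaled lattice: all deep-interior speeds equal."""
        dom, centers, _, _ = hex_sheet
        scale = 1.05
        big = tm.Domain((0.0, 0.0), (10.0 * scale, 10.0 * scale))
        tess, mesh = tm.tessellate_2d(
            tm.CellCenters(centers.coords * scale), big
        )
        deep = [
            a for a in range(mesh.n_vertices)
            if not mesh.is_boundary[a]
            and all(not tess.boundary[k] for k in mesh.vertex_incident_cells[a])
        ]
        p = tm.WOParams(sigma=1.0, kappa=1.0)
        speeds = [np.linalg.norm(tm.wo_vertex_velocity(a, mesh, tess, p)) for a in deep]
        np.testing.assert_allclose(speeds, speeds[0], atol=1e-10)

    def test_boundary_vertex_rejected(self, hex_sheet):
        _, _, tess, mesh = hex_sheet
        b = int(np.nonzero(mesh.is_boundary)[0][0])
        with pytest.raises(ValueError):
            tm.wo_vertex_velocity(b, mesh, tess, tm.WOParams(1.0, 1.0))

    def test_wo_matches_hand_expansion(self, hex_sheet, deep_interior_vertices):
        """Independent expansion of the three-cell sum at a perturbed vertex."""
        _, _, tess, mesh = hex_sheet
        rng = np.random.default_rng(7)
        vols = tess.volumes * rng.uniform(0.9, 1.1, tess.n)
        pers = tess.perimeters * rng.uniform(0.9, 1.1, tess.n)
        geom = CellGeometry(vols, pers)
        p = tm.WOParams(sigma=1.3, kappa=0.7)
        alpha = deep_interior_vertices[0]
        cells = sorted(mesh.vertex_incident_cells[alpha])
        v_hand = np.zeros(2)
        for beta in sorted(mesh.vertex_adjacency[alpha]):
            flank = sorted(mesh.vertex_incident_cells[alpha]
                           & mesh.vertex_incident_cells[beta])
            (k,) = [c for c in cells if c not in flank]
            _, rhat = mesh.edge(alpha, beta)
            v_hand += (p.sigma / vols[k] + p.kappa * (pers[flank[0]] + pers[flank[1]])) * rhat
        np.testing.assert_allclose(
            tm.wo_vertex_velocity(alpha, mesh, geom, p), v_hand, atol=1e-12
        )

    def test_nh_equilibrium(self, hex_sheet, deep_interior_vertices):
        _, _, tess, mesh = hex_sheet
        V0 = math.sqrt(3.0) / 2.0
        a0 = 6.0 / math.sqrt(3.0)
        p = tm.NHParams(lam=1.0, beta=1.0, gamma=0.0, V0=V0, a0=a0)
        geom = CellGeometry(np.full(tess.n, V0), np.full(tess.n, a0))
        for a in deep_interior_vertices[:10]:
            v = tm.nh_vertex_velocity(a, mesh, geom, p)
            np.testing.assert_allclose(v, 0.0, atol=1e-12)


class TestModelMatching:
    def test_wo_from_cbm(self, exp_force):
        # g'(s) = mu for the exponential law; sigma = g'(s) V0^2
        assert tm.match_wo_to_cbm(exp_force, 1.0).sigma == pytest.approx(50.0)
        assert tm.match_wo_to_cbm(exp_force, 2.0).sigma == pytest.approx(200.0)

    def test_nh_from_wo(self):
        p = tm.match_nh_to_wo(tm.WOParams(sigma=1.0, kappa=2.0), V0=1.0, r_edge=1.0)
        assert p.lam == pytest.approx(1.0)
        assert p.beta == pytest.approx(1.0)
        assert p.gamma == 0.0
        with pytest.raises(ValueError):
            tm.match_nh_to_wo(tm.WOParams(1.0, 1.0), V0=0.0, r_edge=1.0)

    def test_nh_wo_first_order_agreement(self, hex_sheet, deep_interior_vertices):
        """Matched NH and WO velocity responses to a cell-area perturbation
        agree to first order: the difference decays quadratically."""
        _, _, tess, mesh = hex_sheet
        h = 1.0
        V0 = math.sqrt(3.0) / 2.0 * h * h
        edge = h / math.sqrt(3.0)
        wo = tm.WOParams(sigma=1.0, kappa=1.0)
        nh = tm.match_nh_to_wo(wo, V0=V0, r_edge=edge, a0=6.0 * edge)
        alpha = deep_interior_vertices[0]
        k = sorted(mesh.vertex_incident_cells[alpha])[0]
        errs = []
        for dV in (1e-2, 1e-3):
            g2 = CellGeometry(tess.volumes.copy(), tess.perimeters.copy())
            g2.volumes[k] += dV
            dwo = (tm.wo_vertex_velocity(alpha, mesh, g2, wo)
                   - tm.wo_vertex_velocity(alpha, mesh, tess, wo))
            dnh = (tm.nh_vertex_velocity(alpha, mesh, g2, nh)
                   - tm.nh_vertex_velocity(alpha, mesh, tess, nh))
            errs.append(np.linalg.norm(dwo - dnh))
        observed_order = math.log10(errs[0] / errs[1])
        assert observed_order > 1.8


class TestForceBridge:
    def test_f_from_cbm_equilibrium(self, exp_force):
        xi2 = tm.xi_factor(2, 6)
        V_eq = (exp_force.s / (2.0 * xi2)) ** 2
        assert tm.f_from_cbm(V_eq, exp_force, 6, xi2) == pytest.approx(0.0, abs=1e-12)

    def test_f_from_cbm_value(self, exp_force):
        xi2 = tm.xi_factor(2, 6)
        expected = -((6 * xi2 / 2) ** 2) * tm.g_exp(2 * xi2 * 1.0, exp_force)
        assert tm.f_from_cbm(1.0, exp_force, 6, xi2) == pytest.approx(expected, rel=1e-14)

    def test_sign_flip_across_equilibrium(self, exp_force):
        xi2 = tm.xi_factor(2, 6)
        V_eq = (exp_force.s / (2.0 * xi2)) ** 2
        assert tm.f_from_cbm(0.8 * V_eq, exp_force, 6, xi2) > 0
        assert tm.f_from_cbm(1.2 * V_eq, exp_force, 6, xi2) < 0
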