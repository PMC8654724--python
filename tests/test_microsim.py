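"""Micro-model integration: fixed points, freezing, conservation, GCL."""

import math

import numpy as np
import pytest

import tissuemech as tm
from tissuemech.microsim import cbm_state, vbm_state, wo1d_state


@pytest.fixture()
def chain_state(exp_force):
    """Equilibrium 1D chain at spacing s = 1."""
    dom = tm.Domain((0.0,), (10.0,))
    centers = tm.CellCenters(np.arange(0.5, 10.0, 1.0))
    return cbm_state(centers, dom)


class TestStepCBM:
    def test_equilibrium_chain_fixed(self, chain_state, exp_force):
        st1 = tm.step_cbm(chain_state, exp_force, 1e-3)
        np.testing.assert_allclose(
            st1.centers.coords, chain_state.centers.coords, atol=1e-12
        )

    def test_zero_dt_identity(self, chain_state, exp_force):
        st1 = tm.step_cbm(chain_state, exp_force, 0.0)
        np.testing.assert_array_equal(st1.centers.coords, chain_state.centers.coords)
        assert st1.t == 0.0

    def test_free_cell_between_frozen_neighbors(self, exp_force):
        dom = tm.Domain((0.0,), (3.5,))
        # free middle cell at distances 1.2 (left) and 1.1 (right)
        centers = tm.CellCenters([0.1, 1.3, 2.4], boundary_mask=[True, False, True])
        st = cbm_state(centers, dom, freeze_boundary=False)
        dt = 1e-3
        st1 = tm.step_cbm(st, exp_force, dt)
        expected = dt * (5.0 * math.exp(-1.0) - 10.0 * math.exp(-2.0))
        assert st1.centers.coords[1, 0] - 1.3 == pytest.approx(expected, rel=1e-10)
        assert st1.centers.coords[0, 0] == 0.1  # frozen
        assert st1.centers.coords[2, 0] == 2.4

    def test_reordering_rejected(self, exp_force):
        # strong repulsion drives the free middle cell past its frozen neighbor
        dom = tm.Domain((0.0,), (10.0,))
        centers = tm.CellCenters([1.0, 1.04, 1.3], boundary_mask=[True, False, True])
        st = cbm_state(centers, dom, freeze_boundary=False)
        with pytest.raises(ValueError, match="reorder"):
            tm.step_cbm(st, exp_force, 1.0)

    def test_center_of_mass_conserved(self, exp_force):
        dom = tm.Domain((0.0, 0.0), (8.0, 8.0))
        rng = np.random.default_rng(11)
        pts = rng.uniform(1.0, 7.0, size=(15, 2))
        st = cbm_state(tm.CellCenters(pts), dom, freeze_boundary=False)
        st.centers.boundary_mask[:] = False
        com0 = st.centers.coords.sum(axis=0)
        for _ in range(100):
            st = tm.step_cbm(st, exp_force, 1e-4, retessellate=False)
        np.testing.assert_allclose(st.centers.coords.sum(axis=0), com0, atol=1e-8)


class TestStepVBM:
    @pytest.fixture()
    def sheet_state(self, hex_sheet):
        dom, centers, _, _ = hex_sheet
        return vbm_state(tm.CellCenters(centers.coords), dom)

    def test_uniform_mesh_near_fixed(self, sheet_state):
        """Interior vertices with uniform hexagon neighborhoods do not move;
        only vertices near the frozen rim feel clipped-cell asymmetry."""
        wo = tm.WOParams(sigma=1.0, kappa=1.0)
        st1 = tm.step_vbm(sheet_state, wo, 1e-4)
        moved = np.linalg.norm(
            st1.mesh.vertex_coords - sheet_state.mesh.vertex_coords, axis=1
        )
        mesh, tess = sheet_state.mesh, sheet_state.geometry
        # vertices whose incident cells all have the uniform hexagon area
        uniform = [
            a for a in range(mesh.n_vertices)
            if not mesh.is_boundary[a]
            and all(
                abs(tess.volumes[k] - math.sqrt(3) / 2) < 1e-9
                and abs(tess.perimeters[k] - 6.0 / math.sqrt(3)) < 1e-9
                for k in mesh.vertex_incident_cells[a]
            )
        ]
        assert len(uniform) > 50
        assert moved[uniform].max() < 1e-12

    def test_zero_dt_identity(self, sheet_state):
        st1 = tm.step_vbm(sheet_state, tm.WOParams(1.0, 1.0), 0.0)
        np.testing.assert_array_equal(
            st1.mesh.vertex_coords, sheet_state.mesh.vertex_coords
        )

    def test_area_change_matches_shoelace(self, sheet_state):
        """Areas after a step equal direct polygon recomputation."""
        from tissuemech.microsim import polygon_geometry

        st1 = tm.step_vbm(sheet_state, tm.WOParams(1.0, 1.0), 1e-4)
        geom = polygon_geometry(st1.mesh.vertex_coords, st1.polygons)
        np.testing.assert_allclose(st1.geometry.volumes, geom.volumes, atol=1e-10)

    def test_frozen_vertices_static(self, sheet_state):
        st1 = tm.step_vbm(sheet_state, tm.WOParams(1.0, 1.0), 1e-3)
        frozen = sheet_state.frozen_vertices
        np.testing.assert_array_equal(
            st1.mesh.vertex_coords[frozen], sheet_state.mesh.vertex_coords[frozen]
        )


class TestStepWO1D:
    def test_uniform_chain_fixed(self):
        dom = tm.Domain((0.0,), (10.0,))
        st = wo1d_state(np.linspace(0.0, 10.0, 11), dom)
        st1 = tm.step_wo_1d(st, 50.0, 1e-4)
        np.testing.assert_array_equal(st1.vertices, st.vertices)

    def test_compressed_cell_expands(self):
        dom = tm.Domain((0.0,), (3.0,))
        st = wo1d_state(np.array([0.0, 1.0, 1.8, 3.0]), dom)
        st1 = tm.step_wo_1d(st, 1.0, 1e-3)
        # middle cell (width 0.8) is densest: both its walls move outward
        assert st1.vertices[1] < 1.0
        assert st1.vertices[2] > 1.8

    def test_ends_frozen(self):
        dom = tm.Domain((0.0,), (3.0,))
        st = wo1d_state(np.array([0.0, 1.0, 1.5, 3.0]), dom)
        st1 = tm.step_wo_1d(st, 1.0, 1e-3)
        assert st1.vertices[0] == 0.0 and st1.vertices[-1] == 3.0


class TestRunAndDensity:
    def test_zero_time_single_frame(self, chain_state, exp_force):
        traj = tm.run(chain_state, tm.SimConfig(dt=1e-3, T=0.0), exp_force)
        assert len(traj) == 1

    def test_deterministic(self, exp_force):
        dom = tm.Domain((0.0,), (10.0,))
        ic = tm.ic_1d(tm.ICSpec1D(N=10, domain=dom, base_density=1.0,
                                  bump_center=5.0, bump_width=2.0, bump_amplitude=0.2))
        cfg = tm.SimConfig(dt=1e-3, T=0.02)
        a = tm.run(cbm_state(ic, dom), cfg, exp_force)
        b = tm.run(cbm_state(ic, dom), cfg, exp_force)
        np.testing.assert_array_equal(a[-1].centers.coords, b[-1].centers.coords)

    def test_density_field_values(self, chain_state):
        pos, rho = tm.density_field(chain_state)
        np.testing.assert_allclose(rho, 1.0, rtol=1e-12)
        # reciprocal identity: sum V_i rho_i = N
        assert np.sum(chain_state.tess.volumes * rho) == pytest.approx(chain_state.centers.n)

    def test_density_hex(self, hex_sheet):
        dom, centers, tess, _ = hex_sheet
        st = cbm_state(centers, dom)
        _, rho = tm.density_field(st)
        interior = ~tess.boundary
        np.testing.assert_allclose(rho[interior], 2.0 / math.sqrt(3.0), rtol=1e-9)

    def test_relaxation_toward_uniform(self, exp_force):
        """A density bump above equilibrium decays monotonically."""
        dom = tm.Domain((0.0,), (18.0,))
        ic = tm.ic_1d(tm.ICSpec1D(N=20, domain=dom, base_density=1.0,
                                  bump_center=9.0, bump_width=4.0, bump_amplitude=0.3))
        st = cbm_state(ic, dom)
        cfg = tm.SimConfig(dt=1.25e-4, T=0.05, save_every=40)
        traj = tm.run(st, cfg, exp_force)
        maxima = [tm.density_field(s)[1].max() for s in traj]
        assert all(b <= a + 1e-12 for a, b in zip(maxima, maxima[1:]))
        assert maxima[-1] < maxima[0]


class TestGCL:
    def test_static_volumes_unchanged(self, chain_state, exp_force):
        V = tm.gcl_volume_update(chain_state, exp_force, 1e-3)
        np.testing.assert_allclose(V, chain_state.tess.volumes, atol=1e-14)

    def test_total_volume_conserved_with_frozen_rim(self, exp_force):
        dom = tm.Domain((0.0,), (12.0,))
        ic = tm.ic_1d(tm.ICSpec1D(N=12, domain=dom, base_density=1.0,
                                  bump_center=6.0, bump_width=3.0, bump_amplitude=0.2))
        st = cbm_state(ic, dom)
        V1 = tm.gcl_volume_update(st, exp_force, 1e-3)
        assert V1.sum() == pytest.approx(st.tess.volumes.sum(), rel=1e-12)

    def test_euler_step_agreement(self, exp_force):
        """GCL volume estimate vs re-tessellated volumes after one Euler step.

        In 1D the interval midpoints move with the mean of the two adjacent
        center velocities, which is exactly the GCL interface velocity, so
        the two volume updates agree to round-off (well inside the O(dt^2)
        bound that holds for a general mesh).
        """
        dom = tm.Domain((0.0,), (12.0,))
        ic = tm.ic_1d(tm.ICSpec1D(N=12, domain=dom, base_density=1.0,
                                  bump_center=6.0, bump_width=3.0, bump_amplitude=0.2))
        for dt in (2e-3, 1e-3):
            st = cbm_state(ic, dom)
            V_gcl = tm.gcl_volume_update(st, exp_force, dt)
            st1 = tm.step_cbm(st, exp_force, dt)
            np.testing.assert_allclose(V_gcl, st1.tess.volumes, atol=1e-12)
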