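"""FE engine: patch tests, tangent consistency, equilibrium, substepping."""

import numpy as np
import pytest

from lvmech import FEModel, OgdenParams, assign_fibers, build_mesh, solve_geometry
from lvmech.fe import BoundaryConditions, FEError, SolverSettings
from lvmech.geometry import cavity_volume_of

from conftest import make_cube_model


C_ACT = 500.0 / 16.93


class TestPatchCube:
    def test_stress_free_state_has_zero_residual(self, cube_model):
        u = np.zeros((9, 3))
        r = cube_model.residual(u, 0.0, 0.0, 100.0)
        assert np.abs(r).max() < 1e-4  # kPa mm^2, machine-zero force scale

    def test_rigid_translation_zero_residual_without_foundation(self, cube_model):
        u = np.tile([1.0, -2.0, 3.0], (9, 1))
        r = cube_model.residual(u, 0.0, 50.0, 100.0)
        assert np.abs(r).max() < 1e-6

    def test_foundation_resists_rigid_translation(self):
        model = make_cube_model(foundation=0.02)
        u = np.tile([0.0, 0.0, 1.0], (9, 1))  # normal to the epi face
        r = model.residual(u, 0.0, 0.0, 100.0)
        # total foundation force = K_f * area * u_n
        fz = r.reshape(-1, 3)[4:8, 2].sum()
        assert fz == pytest.approx(0.02 * 100.0 * 1.0, rel=1e-6)

    def test_tangent_matches_global_finite_differences(self, cube_model):
        rng = np.random.default_rng(1)
        u = 0.05 * rng.standard_normal((9, 3))
        u[8] = 0.0
        p, ea, K = 2.0, 50.0, 300.0
        Kt = cube_model.tangent(u, p, ea, K).toarray()
        h = 1e-5
        Kfd = np.zeros_like(Kt)
        for d in range(24):
            up = u.reshape(-1).copy(); up[d] += h
            um = u.reshape(-1).copy(); um[d] -= h
            Kfd[:, d] = (
                cube_model.residual(up.reshape(-1, 3), p, ea, K, guard=False)
                - cube_model.residual(um.reshape(-1, 3), p, ea, K, guard=False)
            ) / (2 * h)
        err = np.abs(Kt[:24, :24] - Kfd[:24, :24]).max() / np.abs(Kfd).max()
        assert err < 1e-5

    def test_uniaxial_fiber_patch_stress(self):
        # stretch the cube along the fiber; internal force on the loaded face
        # must equal (matrix + fiber) PK1 stress times the reference area
        model = make_cube_model(active_fiber_law="linear")
        lam = 1.02
        u = np.zeros((9, 3))
        u[:, 0] = (lam - 1.0) * model.mesh.nodes[:, 0]
        ea, K = 100.0, 500.0
        f = model.internal_force(u, ea, K).reshape(-1, 3)
        fx = f[[1, 2, 5, 6], 0].sum()  # +x face nodes
        from lvmech.materials import fiber_stress, matrix_stress
        F = np.diag([lam, 1.0, 1.0])
        S = matrix_stress(F, model.ogden, K) + fiber_stress(
            F, np.array([1.0, 0, 0]), ea, 0.7
        )
        P = F @ S
        assert fx == pytest.approx(P[0, 0] * 100.0, rel=1e-5)


class TestSolve:
    def test_unloaded_step_returns_reference(self, tiny_model):
        st = tiny_model.solve_step(tiny_model.initial_state(), 0.0, 0.0, 100.0)
        assert np.abs(st.u).max() < 1e-6
        assert st.volume == pytest.approx(50.0, rel=1e-6)

    def test_inflation_increases_volume_monotonically_in_p(self, tiny_model):
        s0 = tiny_model.initial_state()
        vols = []
        state = s0
        for p in [0.2, 0.4, 0.6]:
            state = tiny_model.solve_step(state, p, C_ACT * p, 1.0)
            vols.append(state.volume)
        assert vols[0] > 50.0
        assert np.all(np.diff(vols) > 0)

    def test_volume_decreases_with_K_at_fixed_pressure(self, tiny_model):
        s0 = tiny_model.initial_state()
        vols = [tiny_model.solve_step(s0, 1.0, C_ACT, K).volume
                for K in [0.3, 1.0, 3.0, 10.0]]
        assert np.all(np.diff(vols) < 0)

    def test_wall_volume_change_shrinks_as_K_grows(self, tiny_model):
        # |integral J dV - V_wall| is non-increasing when K doubles
        import lvmech.elements as el
        gp, w = el.gauss_points(2)
        dN = el.shape_gradients(gp)
        mesh = tiny_model.mesh
        s0 = tiny_model.initial_state()
        changes = []
        for K in [1.0, 2.0, 4.0, 8.0]:
            st = tiny_model.solve_step(s0, 1.0, C_ACT, K)
            x = mesh.nodes + st.u
            J = el.jacobians(x[mesh.elems], dN)
            vol = np.einsum("eg,g->", np.linalg.det(J), w) / 1000.0
            changes.append(abs(vol - 73.6))
        assert np.all(np.diff(changes) <= 1e-9)

    def test_global_equilibrium_reactions_balance_loads(self, tiny_model):
        st = tiny_model.solve_step(tiny_model.initial_state(), 1.0, C_ACT, 1.0)
        r = tiny_model.residual(st.u, st.p, st.e_active, st.K)
        fext = tiny_model.external_force(st.u, st.p)
        # internal forces sum to zero identically, so the residual total
        # (reactions at supports, ~0 at free dofs) balances the applied loads
        np.testing.assert_allclose(
            r.reshape(-1, 3).sum(axis=0),
            -fext.reshape(-1, 3).sum(axis=0),
            atol=1e-6 * np.abs(fext).max(),
        )

    def test_substepping_handles_large_load_jump(self, tiny_model):
        st = tiny_model.solve_step(tiny_model.initial_state(), 10.6, C_ACT * 10.6, 3.0)
        assert st.volume > 100.0  # strongly dilated state reached

    def test_invalid_bulk_modulus_rejected(self, tiny_model):
        with pytest.raises(FEError):
            tiny_model.solve_step(tiny_model.initial_state(), 1.0, 0.0, -5.0)


class TestPreload:
    def test_zero_target_is_identity(self, tiny_model):
        s0 = tiny_model.initial_state()
        assert tiny_model.preload(s0, 0.0) is s0

    def test_ramp_count_invariance(self, tiny_model):
        s0 = tiny_model.initial_state()
        vols = [tiny_model.preload(s0, 0.5, n_ramp=n, K=1.0).volume
                for n in (5, 10, 20)]
        assert max(vols) - min(vols) < 0.005 * min(vols)

    def test_monotone_volume_growth_along_ramp(self, tiny_model):
        state = tiny_model.initial_state()
        vols = [state.volume]
        for i in range(1, 6):
            p = 0.5 * i / 5
            state = tiny_model.solve_step(state, p, C_ACT * p, 1.0)
            vols.append(state.volume)
        assert np.all(np.diff(vols) > 0)


class TestSphericalShellOracle:
    """Inflation of an incompressible isotropic thick spherical shell.

    A hemisphere mesh with the base-plane symmetry condition represents the
    full sphere. The FE pressure-volume response at K = 1e5 * mu_eff is
    compared with the 1-D semi-analytic relation
    P(lam_a) = int_{lam_b}^{lam_a} W'(lam) / (lam^3 - 1) dlam
    for an incompressible Ogden solid.
    """

    @staticmethod
    def oracle_pressure(lam_a, Ra, Rb, params):
        from scipy.integrate import quad
        from lvmech.materials import ogden_energy

        ra3 = (lam_a * Ra) ** 3
        lam_b = ((ra3 - Ra**3 + Rb**3) ** (1.0 / 3.0)) / Rb

        def Wp(lam):
            h = 1e-6
            f = lambda x: ogden_energy([x**-2, x, x], params)
            return (f(lam + h) - f(lam - h)) / (2 * h)

        val, _ = quad(lambda lam: Wp(lam) / (lam**3 - 1.0), lam_b, lam_a)
        return val

    def test_pressure_volume_curve_matches_semi_analytic(self):
        from lvmech import FiberConstituents
        params = OgdenParams(mu=(20.0,), alpha=(2.0,))
        mu_eff = params.shear_modulus
        K = 1e5 * mu_eff
        geom = solve_geometry(16.755, 12.21, aspect_ratio=1.0, truncation_fraction=1.0)
        mesh = build_mesh(geom, 12, 6, 4, calibrate=False)
        field = assign_fibers(mesh)
        model = FEModel(
            mesh, field, ogden=params,
            constituents=FiberConstituents(collagen_E=0.0),
            bcs=BoundaryConditions(foundation_stiffness=0.0),
        )
        # effective radii from the discrete volumes (cancels the surface
        # faceting bias in the comparison)
        from lvmech.geometry import mesh_wall_volume
        v0 = cavity_volume_of(mesh)
        Ra = (3.0 * v0 * 1000.0 / (2.0 * np.pi)) ** (1.0 / 3.0)
        Rb = (3.0 * (v0 + mesh_wall_volume(mesh)) * 1000.0 / (2.0 * np.pi)) ** (1.0 / 3.0)

        state = model.initial_state()
        for lam_a in [1.05, 1.12, 1.2]:
            p = self.oracle_pressure(lam_a, Ra, Rb, params)
            state = model.solve_step(state, p, 0.0, K)
            v_oracle = v0 * lam_a**3
            assert state.volume == pytest.approx(v_oracle, rel=0.02)
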