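"""Constitutive models: energies, stresses, finite-difference consistency."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from lvmech import (
    BulkState,
    FiberConstituents,
    OgdenParams,
    fiber_stress,
    matrix_stress,
    ogden_energy,
    volumetric_energy,
    volumetric_pressure,
)
from lvmech.materials import MaterialError, ogden_dev_2pk


PAR = OgdenParams()


def total_energy(C, K, f0=None, Ef=0.0, vf=0.0, form="quadratic"):
    """Independent scalar energy used as the differentiation oracle."""
    lam = np.sqrt(np.clip(np.linalg.eigvalsh(C), 0, None))
    W = ogden_energy(lam, PAR) + volumetric_energy(np.prod(lam), K, form)
    if f0 is not None:
        eps = 0.5 * (f0 @ C @ f0 - 1.0)
        W += 0.5 * vf * Ef * eps**2
    return W


class TestOgdenEnergy:
    def test_reference_state_zero(self):
        assert ogden_energy([1.0, 1.0, 1.0], PAR) == 0.0

    def test_small_strain_shear_modulus(self):
        # G = (mu1 a1 + mu2 a2)/2 = 2083.4 kPa, recovered by finite
        # differencing W at an infinitesimal simple shear
        g = 1e-5
        lam_max = g / 2 + np.sqrt(1 + g**2 / 4)  # principal stretches of shear
        lams = np.array([lam_max, 1.0, 1.0 / lam_max])
        W = ogden_energy(lams, PAR)
        G_fd = 2 * W / g**2
        assert PAR.shear_modulus == pytest.approx(2083.4, abs=0.05)
        assert G_fd == pytest.approx(PAR.shear_modulus, rel=1e-3)

    def test_permutation_invariance(self):
        lams = [1.3, 0.9, 1.05]
        vals = {ogden_energy(np.array(lams)[list(p)], PAR)
                for p in [(0, 1, 2), (1, 2, 0), (2, 0, 1), (0, 2, 1)]}
        assert max(vals) - min(vals) < 1e-12

    def test_isochoric_reduction(self):
        # scaling all stretches leaves the (isochoric) energy unchanged
        lams = np.array([1.2, 0.95, 1.1])
        assert ogden_energy(2.0 * lams, PAR) == pytest.approx(
            ogden_energy(lams, PAR), rel=1e-12
        )

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(MaterialError):
            ogden_energy([1.0, -0.5, 1.0], PAR)


class TestVolumetric:
    @pytest.mark.parametrize("form", ["quadratic", "log"])
    def test_reference_state(self, form):
        assert volumetric_energy(1.0, 1000.0, form) == 0.0
        assert volumetric_pressure(1.0, 1000.0, form) == 0.0

    def test_quadratic_pressure_value(self):
        # dU/dJ at J=0.99, K=1000 kPa; hydrostatic pressure = -dU/dJ = +10
        assert -volumetric_pressure(0.99, 1000.0) == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize("form", ["quadratic", "log"])
    def test_derivative_matches_finite_difference(self, form):
        J, K, h = 1.17, 730.0, 1e-7
        fd = (volumetric_energy(J + h, K, form) - volumetric_energy(J - h, K, form)) / (2 * h)
        assert volumetric_pressure(J, K, form) == pytest.approx(fd, rel=1e-6)

    def test_linear_in_K(self):
        assert volumetric_energy(1.1, 2000.0) == pytest.approx(
            2 * volumetric_energy(1.1, 1000.0)
        )

    @pytest.mark.parametrize("form", ["quadratic", "log"])
    def test_tangent_bulk_modulus_at_reference_is_K(self, form):
        from lvmech.materials import volumetric_stiffness
        assert volumetric_stiffness(1.0, 777.0, form) == pytest.approx(777.0)

    def test_bulk_state_reciprocal(self):
        assert BulkState(400.0).compressibility == pytest.approx(1 / 400.0)
        with pytest.raises(MaterialError):
            BulkState(-1.0)


class TestMatrixStress:
    def test_zero_at_identity(self):
        S = matrix_stress(np.eye(3), PAR, K=500.0)
        assert np.abs(S).max() < 1e-10

    def test_pure_dilation_is_hydrostatic(self):
        S = matrix_stress(1.1 * np.eye(3), PAR, K=500.0)
        assert np.abs(S - S[0, 0] * np.eye(3)).max() < 1e-10

    def test_energy_consistency_at_random_states(self):
        # S = 2 dW/dC against central differences, 100 random states
        rng = np.random.default_rng(7)
        K, h = 480.0, 1e-6
        worst = 0.0
        for _ in range(100):
            F = np.eye(3) + 0.08 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.2:
                continue
            C = F.T @ F
            S = matrix_stress(F, PAR, K)
            Sfd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    dC = np.zeros((3, 3))
                    dC[i, j] += h / 2
                    dC[j, i] += h / 2
                    Sfd[i, j] = (
                        2 * (total_energy(C + dC, K) - total_energy(C - dC, K)) / (2 * h)
                    )
            worst = max(worst, np.abs(S - Sfd).max() / np.abs(Sfd).max())
        assert worst < 1e-5

    def test_frame_indifference(self):
        rng = np.random.default_rng(11)
        F = np.eye(3) + 0.07 * rng.standard_normal((3, 3))
        for seed in range(5):
            Q = ortho_group.rvs(3, random_state=seed)
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            # 2nd PK stress is invariant under superposed rotations
            np.testing.assert_allclose(
                matrix_stress(Q @ F, PAR, 300.0), matrix_stress(F, PAR, 300.0),
                atol=1e-9 * 1e3,
            )

    def test_polynomial_stress_path_matches_spectral(self):
        # the fast projector-based evaluation against the eigh route,
        # including degenerate stretch states
        rng = np.random.default_rng(5)
        Fs = np.concatenate([
            np.eye(3) + 0.1 * rng.standard_normal((20, 3, 3)),
            [np.diag([1.2, 1.2, 0.9]), np.eye(3), 1.3 * np.eye(3)],
        ])
        J = np.linalg.det(Fs)
        C = np.einsum("...ki,...kj->...ij", Fs, Fs)
        S_poly = ogden_dev_2pk(C, J, PAR)
        S_ref = matrix_stress(Fs, PAR, K=1.0) - (
            volumetric_pressure(J, 1.0) * J
        )[..., None, None] * np.linalg.inv(C)
        scale = max(np.abs(S_ref).max(), 1.0)
        assert np.abs(S_poly - S_ref).max() / scale < 1e-5

    def test_non_invertible_F_rejected(self):
        with pytest.raises(MaterialError):
            matrix_stress(np.diag([1.0, 1.0, 0.0]), PAR, 100.0)


class TestFiberStress:
    def test_zero_strain_zero_stress(self):
        f0 = np.array([1.0, 0, 0])
        assert np.abs(fiber_stress(np.eye(3), f0, 30.0, 0.7)).max() == 0.0

    def test_uniaxial_stretch_closed_form(self):
        # S_ff = v_f E_f (lam^2 - 1)/2 from the Green-Lagrange strain
        lam, Ef, vf = 1.25, 40.0, 0.7
        F = np.diag([lam, 1.0, 1.0])
        f0 = np.array([1.0, 0, 0])
        S = fiber_stress(F, f0, Ef, vf)
        assert S[0, 0] == pytest.approx(vf * Ef * (lam**2 - 1) / 2, rel=1e-12)
        assert np.abs(S - np.diag([S[0, 0], 0, 0])).max() == 0.0

    def test_zero_modulus_gives_passive_matrix_only(self):
        F = np.diag([1.3, 0.9, 1.0])
        assert np.abs(fiber_stress(F, np.array([1.0, 0, 0]), 0.0, 0.7)).max() == 0.0

    @pytest.mark.parametrize(
        "branch,lam,active",
        [("tension", 1.2, True), ("tension", 0.9, False),
         ("compression", 1.2, False), ("compression", 0.9, True),
         ("linear", 0.9, True)],
    )
    def test_strain_branches(self, branch, lam, active):
        F = np.diag([lam, 1.0, 1.0])
        S = fiber_stress(F, np.array([1.0, 0, 0]), 50.0, 0.7, branch=branch)
        assert (np.abs(S).max() > 0) == active

    def test_non_unit_direction_rejected(self):
        with pytest.raises(MaterialError):
            fiber_stress(np.eye(3), np.array([1.0, 1.0, 0.0]), 10.0, 0.5)

    def test_constituent_validation(self):
        with pytest.raises(MaterialError):
            FiberConstituents(vf_myo=0.99, vf_collagen=0.02)
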