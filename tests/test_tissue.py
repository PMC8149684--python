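"""St. Venant-Kirchhoff kernels, Robin coefficients and the surrogate-shell
Young's-modulus calibration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lumpedheart.errors import CalibrationError, DomainError
from lumpedheart.tissue import (MaterialParams, SphericalShellChamber,
                                calibrate_young_modulus,
                                cauchy_from_second_piola, green_lagrange_strain,
                                lame_constants, lame_to_young,
                                robin_coefficients, svk_second_piola)

I3 = np.eye(3)


class TestLameConstants:
    def test_hand_values(self):
        lam, mu = lame_constants(1e5, 0.3)
        assert lam == pytest.approx(57692.30769230769, rel=1e-12)
        assert mu == pytest.approx(38461.53846153846, rel=1e-12)

    def test_zero_poisson_decouples(self):
        lam, mu = lame_constants(2e5, 0.0)
        assert lam == 0.0
        assert mu == pytest.approx(1e5)

    def test_round_trip(self):
        lam, mu = lame_constants(8.2e4, 0.27)
        E, nu = lame_to_young(lam, mu)
        assert E == pytest.approx(8.2e4, rel=1e-12)
        assert nu == pytest.approx(0.27, rel=1e-12)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(DomainError):
            lame_constants(1e5, 0.5)


class TestGreenLagrangeStrain:
    def test_undeformed_is_strain_free(self):
        assert np.allclose(green_lagrange_strain(I3), 0.0)

    def test_uniaxial_stretch(self):
        F = np.diag([1.1, 1.0, 1.0])
        E = green_lagrange_strain(F)
        assert E[0, 0] == pytest.approx(0.105, rel=1e-12)
        assert abs(E).sum() == pytest.approx(0.105)

    def test_rotation_objectivity(self, rng):
        # rigid rotations produce exactly zero strain, and rotating any
        # deformation leaves the strain unchanged (E depends on FᵀF only)
        F = I3 + 0.1 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.1:
            F = I3
        E_F = green_lagrange_strain(F)
        for R in Rotation.random(100, rng=rng).as_matrix():
            assert np.abs(green_lagrange_strain(R)).max() < 1e-12
            assert np.abs(green_lagrange_strain(R @ F) - E_F).max() < 1e-12

    def test_inverted_element_rejected(self):
        with pytest.raises(DomainError):
            green_lagrange_strain(np.diag([-1.0, 1.0, 1.0]))


class TestSecondPiola:
    def test_zero_strain_zero_stress(self):
        assert np.allclose(svk_second_piola(np.zeros((3, 3)), 5e4, 4e4), 0.0)

    def test_hydrostatic_closed_form(self):
        lam, mu, eps = 5.0e4, 3.0e4, 0.01
        S = svk_second_piola(eps * I3, lam, mu)
        assert np.allclose(S, (3 * lam + 2 * mu) * eps * I3, rtol=1e-12)

    def test_pure_shear_closed_form(self):
        lam, mu, gamma = 5.0e4, 3.0e4, 0.02
        E = np.zeros((3, 3))
        E[0, 1] = E[1, 0] = gamma / 2
        S = svk_second_piola(E, lam, mu)
        assert S[0, 1] == pytest.approx(mu * gamma, rel=1e-12)
        assert S[0, 0] == 0.0

    def test_asymmetric_strain_rejected(self):
        E = np.zeros((3, 3))
        E[0, 1] = 1e-3
        with pytest.raises(DomainError):
            svk_second_piola(E, 5e4, 3e4)


class TestCauchyPushForward:
    def test_identity_push_forward(self):
        S = np.diag([1.0, 2.0, 3.0])
        assert np.allclose(cauchy_from_second_piola(I3, S), S)

    def test_rotation_preserves_invariants(self, rng):
        S = svk_second_piola(0.01 * I3 + np.diag([0.002, 0.0, -0.001]),
                             5e4, 3e4)
        for R in Rotation.random(20, rng=rng).as_matrix():
            sigma = cauchy_from_second_piola(R, S)
            assert np.allclose(sigma, R @ S @ R.T, atol=1e-8)
            assert np.trace(sigma) == pytest.approx(np.trace(S), rel=1e-12)
            assert np.linalg.det(sigma) == pytest.approx(np.linalg.det(S),
                                                         rel=1e-9)

    def test_isotropic_scaling(self):
        S = np.diag([7.0, 1.0, -2.0])
        c = 1.3
        # det F = c³, F·Σ·Fᵀ = c²Σ → σ = Σ/c
        assert np.allclose(cauchy_from_second_piola(c * I3, S), S / c)


class TestSmallStrainAndEnergy:
    def test_small_strain_matches_linear_elasticity(self, rng):
        lam, mu = lame_constants(6e4, 0.3)
        grad_u = 1e-4 * rng.standard_normal((3, 3))
        F = I3 + grad_u.T  # F = I + (∇u)ᵀ convention
        E = green_lagrange_strain(F)
        S = svk_second_piola(E, lam, mu)
        eps = 0.5 * (grad_u + grad_u.T)
        sigma_lin = lam * np.trace(eps) * I3 + 2 * mu * eps
        assert np.abs(S - sigma_lin).max() <= 1e-3 * np.abs(sigma_lin).max()

    def test_stress_power_nonneg_along_proportional_loading(self):
        lam, mu = lame_constants(6e4, 0.25)
        E_dir = np.diag([0.03, -0.01, 0.005])
        prev = 0.0
        for s in np.linspace(0.1, 1.0, 10):
            S = svk_second_piola(s * E_dir, lam, mu)
            power = float(np.tensordot(S, E_dir))  # Σ : dE/ds along the path
            assert power >= 0.0
            assert power >= prev  # monotone for the quadratic SVK energy
            prev = power


class TestRobinCoefficients:
    def test_hand_value(self):
        # λ+2µ = 1e6 Pa at ν = 0.25, E = 8e5 → ... use explicit material
        mat = MaterialParams(young_E=1e5, poisson_nu=0.3, rho_s=1000.0)
        lam_p2mu = mat.lame_lambda + 2 * mat.lame_mu
        out = robin_coefficients(1e-4, mat, rho_fluid=1060.0)
        assert out["h_s"] == pytest.approx(1e-4 * np.sqrt(lam_p2mu / 1000.0),
                                           rel=1e-12)
        assert out["alpha"] == pytest.approx(1000.0 * out["h_s"] / 1060.0,
                                             rel=1e-12)

    def test_wave_speed_scaling_example(self):
        # (λ+2µ)/ρ_s = 1e6/1000 → h_s = Δt·√1000 ≈ 3.1623e-3 m at Δt 1e-4
        mat = MaterialParams(young_E=1e5, poisson_nu=0.3, rho_s=1000.0)
        scale = 1e6 / (mat.lame_lambda + 2 * mat.lame_mu)
        out = robin_coefficients(1e-4 , MaterialParams(
            young_E=1e5 * scale, poisson_nu=0.3, rho_s=1000.0), 1060.0)
        assert out["h_s"] == pytest.approx(3.1622776601683794e-3, rel=1e-12)

    def test_vanishing_time_step_limit(self):
        mat = MaterialParams(young_E=1e5, poisson_nu=0.3)
        out = robin_coefficients(1e-12, mat, 1060.0)
        assert out["h_s"] < 1e-9
        assert out["alpha"] < 1e-9

    def test_homogeneity_in_densities(self):
        m1 = MaterialParams(young_E=1e5, poisson_nu=0.3, rho_s=1000.0)
        m4 = MaterialParams(young_E=1e5, poisson_nu=0.3, rho_s=4000.0)
        a1 = robin_coefficients(1e-4, m1, 1000.0)
        a4 = robin_coefficients(1e-4, m4, 1000.0)
        # h_s ∝ 1/√ρ_s and α ∝ ρ_s·h_s → α ∝ √ρ_s
        assert a4["h_s"] == pytest.approx(a1["h_s"] / 2, rel=1e-12)
        assert a4["alpha"] == pytest.approx(2 * a1["alpha"], rel=1e-12)
        half_fluid = robin_coefficients(1e-4, m1, 500.0)
        assert half_fluid["alpha"] == pytest.approx(2 * a1["alpha"], rel=1e-12)


class TestShellCalibration:
    CHAMBER = SphericalShellChamber(unloaded_volume_ml=90.0,
                                    wall_thickness_cm=1.0, poisson_nu=0.3)

    def test_unloaded_volume_is_pressure_free(self):
        for E in (2e4, 6e4, 2e5):
            assert self.CHAMBER.pressure_mmhg(90.0, E) == pytest.approx(0.0)

    def test_stiffer_wall_higher_pressure_at_volume(self):
        V = np.linspace(95.0, 140.0, 10)
        p1 = self.CHAMBER.pressure_mmhg(V, 3e4)
        p2 = self.CHAMBER.pressure_mmhg(V, 6e4)
        assert np.all(p2 > p1)

    def test_round_trip_recovery(self):
        E_true = 60e3  # Pa
        V = np.linspace(92.0, 135.0, 25)
        P = self.CHAMBER.pressure_mmhg(V, E_true)
        out = calibrate_young_modulus(P, V, self.CHAMBER)
        assert out["young_E"] == pytest.approx(E_true, rel=0.02)
        assert out["l2_mismatch_mmhg"] < 1e-6

    def test_no_bracket_reported(self):
        V = np.linspace(92.0, 135.0, 10)
        P = self.CHAMBER.pressure_mmhg(V, 60e3)
        with pytest.raises(CalibrationError):
            calibrate_young_modulus(P, V, self.CHAMBER, bracket_pa=(1e8, 1e9))
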