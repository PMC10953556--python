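"""Fiber stresses, volume-fraction kinetics, nuclear balance, orientation field."""

import numpy as np
import pytest

from yapflow import mechanics as mech


@pytest.fixture(scope="module")
def params():
    return mech.MechanicsParams()


@pytest.fixture(scope="module")
def geometry():
    return mech.CellGeometry()


class TestFiberStress:
    def test_passive_term_vanishes(self, params):
        assert mech.fiber_stress(0.0, 0.4, 10.0, params) == pytest.approx(
            params.k_sigma_myo * 0.4)

    def test_active_term_vanishes(self, params):
        assert mech.fiber_stress(0.05, 0.0, 10.0, params) == pytest.approx(0.5)

    def test_linear_decomposition_exact(self, params):
        e, m = 0.03, 0.7
        total = mech.fiber_stress(e, m, 12.0, params)
        assert total == mech.fiber_stress(e, 0.0, 12.0, params) + \
            mech.fiber_stress(0.0, m, 12.0, params)

    def test_nonpositive_stiffness_raises(self, params):
        with pytest.raises(ValueError):
            mech.fiber_stress(0.1, 0.1, 0.0, params)


class TestCfVolumeFraction:
    def test_decays_to_zero_without_f_actin(self, params):
        rho = 0.3
        for _ in range(5):
            rho = mech.step_cf_volume_fraction(rho, 0.0, params.tau_rho, params)
        assert rho < 0.01 * 0.3

    def test_converges_to_target_within_5_time_constants(self, params):
        target = mech.cf_volume_fraction_target(0.8, params)
        rho = mech.step_cf_volume_fraction(0.0, 0.8, 5 * params.tau_rho, params)
        assert abs(rho - target) < 0.01 * target

    def test_stepper_matches_closed_form(self, params):
        rho, t = 0.05, 0.0
        for _ in range(137):
            rho = mech.step_cf_volume_fraction(rho, 0.6, 37.0, params)
            t += 37.0
        target = mech.cf_volume_fraction_target(0.6, params)
        assert rho == pytest.approx(
            mech.cf_volume_fraction_analytic(0.05, target, t, params), rel=1e-6)

    def test_target_clipped_to_rho_max(self, params):
        assert mech.cf_volume_fraction_target(100.0, params) == params.rho_max


class TestAnisotropyCoefficient:
    def test_isotropic_is_one(self):
        assert mech.anisotropy_coefficient(1.3, 1.3) == 1.0

    def test_definition(self):
        assert mech.anisotropy_coefficient(2.0, 1.0) == 2.0

    def test_zero_perpendicular_raises(self):
        with pytest.raises(ValueError):
            mech.anisotropy_coefficient(1.0, 0.0)


class TestNuclearStressBalance:
    def test_no_cap_limit(self, params, geometry):
        g = mech.geometric_projection_factor(geometry)
        ms = mech.nuclear_stress_balance(1.2, 0.2, 1.5, 0.0, 20.0, 1.0,
                                         params, geometry)
        assert ms.sigma_LINC == 0.0
        assert ms.epsilon_NM_eq == pytest.approx(g * 0.2 * 1.2 / 1.0)

    def test_rigid_nucleus_limit(self, params, geometry):
        ms = mech.nuclear_stress_balance(1.2, 0.2, 1.5, 0.1, 20.0, 1e12,
                                         params, geometry)
        assert ms.epsilon_NM_eq < 1e-12

    def test_zero_stress_zero_strain(self, params, geometry):
        ms = mech.nuclear_stress_balance(0.0, 0.2, 0.0, 0.1, 20.0, 1.0,
                                         params, geometry)
        assert ms.epsilon_NM_eq == 0.0

    def test_monotonicity_contracts_on_grid(self, params, geometry):
        """Finite-difference signs of the four guaranteed partials."""
        h = 1e-6
        rho_caps = np.linspace(0.0, 0.5, 10)
        e_nucs = np.linspace(0.5, 3.0, 10)
        k_caps = np.linspace(5.0, 60.0, 10)

        def balance(rho_cap, e_nuc, k_cap):
            return mech.nuclear_stress_balance(
                1.1, 0.2, 1.6, rho_cap, k_cap, e_nuc, params, geometry)

        for rho_cap in rho_caps:
            for e_nuc in e_nucs[::3]:
                for k_cap in k_caps[::3]:
                    base = balance(rho_cap, e_nuc, k_cap)
                    up = balance(rho_cap + h, e_nuc, k_cap)
                    assert up.sigma_LINC >= base.sigma_LINC - 1e-12
                    assert up.sigma_NM_mean <= base.sigma_NM_mean + 1e-12
                    assert (balance(rho_cap, e_nuc + h, k_cap).epsilon_NM_eq
                            < base.epsilon_NM_eq or base.epsilon_NM_eq == 0)
                    assert (balance(rho_cap, e_nuc, k_cap + h).epsilon_NM_eq
                            <= base.epsilon_NM_eq + 1e-15)

    def test_nonpositive_modulus_raises(self, params, geometry):
        with pytest.raises(ValueError):
            mech.nuclear_stress_balance(1.0, 0.2, 1.0, 0.1, 20.0, 0.0,
                                        params, geometry)


class TestBasalTraction:
    def test_zero_stress_zero_traction(self, params):
        assert mech.basal_traction(0.0, 0.3, params) == 0.0

    def test_proportionality_recoverable(self, params):
        t1 = mech.basal_traction(1.0, 0.2, params)
        t2 = mech.basal_traction(2.0, 0.2, params)
        assert t2 / t1 == pytest.approx(2.0)


class TestOrientationField:
    def test_unit_directions_and_bounded_potential(self, geometry):
        field = mech.fiber_orientation_field(geometry, 48)
        ok = ~np.isnan(field.direction[..., 0])
        norms = np.hypot(field.direction[..., 0][ok], field.direction[..., 1][ok])
        assert np.allclose(norms, 1.0, atol=1e-12)
        phi = field.potential[field.domain]
        assert phi.min() >= -1e-12 and phi.max() <= 1.0 + 1e-12   # max principle
        assert 0.0 <= field.orientation_order <= 1.0

    def test_grid_refinement_agreement_within_2pct(self, geometry):
        coarse = mech.fiber_orientation_field(geometry, 48)
        fine = mech.fiber_orientation_field(geometry, 96)
        from scipy.interpolate import RegularGridInterpolator
        interp = RegularGridInterpolator((fine.z, fine.r), fine.potential,
                                         bounds_error=False)
        pts = np.array(np.meshgrid(coarse.z, coarse.r, indexing="ij"))
        vals = interp(pts.reshape(2, -1).T).reshape(coarse.potential.shape)
        mask = coarse.domain & ~np.isnan(vals)
        rms = float(np.sqrt(np.mean((coarse.potential[mask] - vals[mask]) ** 2)))
        assert rms < 0.02          # potential spans [0, 1]

    def test_too_coarse_grid_rejected(self, geometry):
        with pytest.raises(ValueError):
            mech.fiber_orientation_field(geometry, 6)


def test_geometry_validation():
    with pytest.raises(ValueError):
        mech.CellGeometry(nucleus_height=10.0)    # taller than the cell
    with pytest.raises(ValueError):
        mech.CellGeometry(gaussian_width=-1.0)
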