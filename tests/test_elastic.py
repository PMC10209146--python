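"""Energy density, tension, prefusion references, and unit handling."""

import numpy as np
import pytest

from hemifusion import (CompartmentSpec, LipidComponent, MaterialParams,
                        energy_density, mean_intrinsic_curvature,
                        monolayer_tension, prefusion_energy)
from hemifusion.elastic import CompositionError
from hemifusion.units import KBT_PN_NM, parse_quantity


class TestUnits:
    def test_stretching_modulus_conversion(self):
        p = MaterialParams(K_m="80 mN/m")
        assert np.isclose(p.K_m, 80.0 / KBT_PN_NM)

    def test_line_tension_conversion(self):
        p = MaterialParams(lambda_rim="15 pN")
        assert np.isclose(p.lambda_rim, 15.0 / KBT_PN_NM)

    def test_plain_numbers_pass_through(self):
        assert parse_quantity(3.25) == 3.25
        assert parse_quantity("10 kBT") == 10.0

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            parse_quantity("7 furlongs")

    @pytest.mark.parametrize("field, value", [
        ("kappa_m", -1.0), ("chi", 0.5), ("chi", -1.5), ("l", 0.0),
        ("delta0", -1.0),
    ])
    def test_parameter_validation(self, field, value):
        with pytest.raises(ValueError):
            MaterialParams(**{field: value})


class TestMeanIntrinsicCurvature:
    def test_single_component(self):
        assert mean_intrinsic_curvature(
            [LipidComponent(zeta=-0.1, mole_fraction=1.0)]) == -0.1

    def test_equimolar_mixture(self):
        comps = [LipidComponent(-0.1, 0.5), LipidComponent(-0.3, 0.5)]
        assert np.isclose(mean_intrinsic_curvature(comps), -0.2)

    def test_fraction_sum_violation(self):
        with pytest.raises(CompositionError):
            mean_intrinsic_curvature(
                [LipidComponent(-0.1, 0.6), LipidComponent(-0.3, 0.3)])


class TestEnergyDensity:
    def test_reference_state_is_zero(self, params):
        assert energy_density(0.0, 0.0, np.zeros(3), 0.0, params) == 0.0

    def test_tilt_free_sphere_monolayer(self):
        p = MaterialParams(kappa_m=10.0, J_sm=-0.22, chi=-0.5)
        u = energy_density(0.1, 0.0025, np.zeros(3), 0.0, p)
        assert np.isclose(u, 0.05 + 0.22 - 0.0125)

    def test_pure_tilt(self):
        p = MaterialParams(kappa_m=10.0, l=1.2)
        u = energy_density(0.0, 0.0, np.array([0.5, 0.0, 0.0]), 0.0, p)
        assert np.isclose(u, 0.5 * (10.0 / 1.44) * 0.25)

    def test_density_minimized_at_spontaneous_splay(self, params):
        Js = params.J_sm
        us = [energy_density(J, 0.0, np.zeros(3), 0.0, params)
              for J in (Js - 0.01, Js, Js + 0.01)]
        assert us[1] < us[0] and us[1] < us[2]


class TestMonolayerTension:
    def test_relaxed_area_gives_zero(self):
        gamma, e = monolayer_tension(100.0, 100.0, 19.45)
        assert gamma == 0.0 and e == 0.0

    def test_small_strain_tension_units(self):
        K = 80.0 / KBT_PN_NM
        gamma, _ = monolayer_tension(1000.0 * 1.001, 1000.0, K)
        assert np.isclose(gamma * KBT_PN_NM, 0.080, rtol=1e-6)  # mN/m

    def test_compression_is_penalized_symmetrically(self):
        K = 19.45
        _, e_plus = monolayer_tension(1001.0, 1000.0, K)
        gamma, e_minus = monolayer_tension(999.0, 1000.0, K)
        assert gamma < 0.0
        assert np.isclose(e_plus, e_minus, rtol=1e-6)

    def test_tension_is_energy_derivative(self):
        K, A0 = 19.45, 1000.0
        dA = 1e-3
        g, _ = monolayer_tension(A0 + 2.0, A0, K)
        _, e1 = monolayer_tension(A0 + 2.0 - dA, A0, K)
        _, e2 = monolayer_tension(A0 + 2.0 + dA, A0, K)
        assert np.isclose((e2 - e1) / (2 * dA), g, rtol=1e-6)


class TestPrefusionEnergy:
    def test_flat_is_zero(self, params, flat):
        assert prefusion_energy(flat, params) == 0.0

    def test_sphere_closed_form(self, params, sphere20):
        # 16πκ(1 − δ0 Jsm) + 8πκ̄ with the reference parameter set
        expected = (16 * np.pi * 10.0 * (1 + 1.5 * 0.22)
                    + 8 * np.pi * (-5.0))
        assert np.isclose(prefusion_energy(sphere20, params), expected)

    def test_sphere_fig4_values(self):
        p = MaterialParams(J_sm=-0.22)
        # radius independence of the closed form
        for R in (20.0, 40.0):
            c = CompartmentSpec(kind="sphere", R_c=R)
            assert np.isclose(prefusion_energy(c, p),
                              prefusion_energy(CompartmentSpec(kind="sphere",
                                                               R_c=20.0), p))

    def test_cylinder_closed_form(self, params):
        c = CompartmentSpec(kind="cylinder", R_c=20.0, L=100.0)
        expected = 2 * np.pi * 10.0 * 20.0 * 100.0 / (400.0 - 2.25)
        assert np.isclose(prefusion_energy(c, params), expected)

    def test_cylinder_radius_must_exceed_tail_length(self, params):
        c = CompartmentSpec(kind="cylinder", R_c=1.2, L=100.0)
        with pytest.raises(ValueError):
            prefusion_energy(c, params)


class TestQuadratureAgainstClosedForms:
    """Full-surface quadrature of the analytic fixtures reproduces the
    closed-form prefusion energies (Eq.-level oracle for the machinery)."""

    def test_sphere_quadrature_matches_closed_form(self, params):
        from hemifusion.fixtures import generate_fixture
        from hemifusion.geometry import monolayer_grids
        fx = generate_fixture("analytic_sphere", params, R=20.0, rho_out=10.0)
        # energy density is constant on a sphere: evaluate and scale to the
        # full sphere area
        total = 0.0
        for side, sign in (("outer", +1), ("inner", -1)):
            g = monolayer_grids(fx.payload, side, nx=32)
            Rd = 20.0 + sign * params.delta0
            u = (0.5 * params.kappa_m * g["J"] ** 2
                 - params.kappa_m * g["J"] * params.J_sm
                 + params.kappa_bar * g["K"])
            dens = float(u.mean())
            total += dens * 4.0 * np.pi * Rd ** 2
        assert np.isclose(total, fx.expected["U0_full_sphere"], rtol=1e-3)
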