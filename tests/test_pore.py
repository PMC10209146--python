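"""Pore energetics: closed-form oracles, monotonicity, Arrhenius ratios."""

import numpy as np
import pytest

from hemifusion import MaterialParams, pore_energy_profile, rate_ratio
from hemifusion.fixtures import generate_fixture
from hemifusion.pore import StressMap, pore_barrier


class TestConstantStressOracle:
    def test_barrier_matches_pi_lambda_sq_over_sigma(self, params):
        fx = generate_fixture("constant_stress_map", params, sigma=1.0)
        prof = pore_energy_profile(fx.payload, params.lambda_rim)
        assert np.isclose(prof.E_pore, fx.expected["E_pore"], rtol=1e-6)
        assert np.isclose(prof.rho_c, fx.expected["rho_c"], rtol=1e-4)

    def test_quadrature_matches_closed_form_profile(self, params):
        fx = generate_fixture("constant_stress_map", params, sigma=0.7)
        prof = pore_energy_profile(fx.payload, params.lambda_rim)
        closed = (2 * np.pi * prof.rho * params.lambda_rim
                  - np.pi * prof.rho ** 2 * 0.7)
        assert np.allclose(prof.U, closed, atol=1e-6 * np.abs(closed).max())

    def test_doubling_sigma_halves_barrier_and_radius(self, params):
        f1 = generate_fixture("constant_stress_map", params, sigma=1.0)
        f2 = generate_fixture("constant_stress_map", params, sigma=2.0)
        p1 = pore_energy_profile(f1.payload, params.lambda_rim)
        p2 = pore_energy_profile(f2.payload, params.lambda_rim)
        assert np.isclose(p2.E_pore, 0.5 * p1.E_pore, rtol=1e-4)
        assert np.isclose(p2.rho_c, 0.5 * p1.rho_c, rtol=1e-3)

    def test_radial_stress_map_oracle(self, params):
        fx = generate_fixture("radial_stress_map", params)
        prof = pore_energy_profile(fx.payload, params.lambda_rim)
        assert np.isclose(prof.E_pore, fx.expected["E_pore"], rtol=1e-4)


class TestProfileProperties:
    def test_profile_starts_at_zero(self, params):
        fx = generate_fixture("constant_stress_map", params, sigma=1.3)
        prof = pore_energy_profile(fx.payload, params.lambda_rim)
        assert prof.U[0] == 0.0

    def test_zero_stress_profile_is_strictly_increasing(self, params):
        fx = generate_fixture("constant_stress_map", params, sigma=0.0)
        prof = pore_energy_profile(fx.payload, params.lambda_rim)
        assert np.all(np.diff(prof.U) > 0)
        assert prof.rim_limited

    def test_barrier_monotone_in_line_tension(self, params):
        fx = generate_fixture("constant_stress_map", params, sigma=1.0)
        barriers = [pore_energy_profile(fx.payload, lam).E_pore
                    for lam in (2.0, 3.0, 4.0)]
        assert barriers[0] < barriers[1] < barriers[2]

    def test_barrier_monotone_in_stress(self, params):
        barriers = []
        for s in (0.5, 1.0, 2.0):
            fx = generate_fixture("constant_stress_map", params, sigma=s)
            barriers.append(pore_energy_profile(fx.payload,
                                                params.lambda_rim).E_pore)
        assert barriers[0] > barriers[1] > barriers[2]

    def test_negative_line_tension_rejected(self, params):
        fx = generate_fixture("constant_stress_map", params, sigma=1.0)
        with pytest.raises(ValueError):
            pore_energy_profile(fx.payload, -1.0)

    def test_phi_collapsed_equals_2d_quadrature(self, params):
        # an axisymmetric 2-D map and its 1-D collapse agree
        n, rim = 80, 8.0
        rho = np.linspace(0, rim, n)
        sig = 0.3 + 0.05 * rho
        m1 = StressMap(rho=rho, phi=np.array([0.0]), sigma=sig[:, None],
                       u0=0.0, rim_radius=np.array([rim]))
        nphi = 16
        m2 = StressMap(rho=np.tile(rho[:, None], (1, nphi)),
                       phi=np.arange(nphi) * 2 * np.pi / nphi,
                       sigma=np.tile(sig[:, None], (1, nphi)), u0=0.0,
                       rim_radius=np.full(nphi, rim))
        p1 = pore_energy_profile(m1, params.lambda_rim)
        p2 = pore_energy_profile(m2, params.lambda_rim)
        assert np.allclose(p1.U, p2.U, atol=1e-8 * max(1.0, np.abs(p1.U).max()))


class TestRateRatio:
    def test_equal_barriers_give_unity(self):
        assert rate_ratio(20.0, 20.0) == 1.0

    def test_log_ten_barrier_difference(self):
        assert np.isclose(rate_ratio(10.0, 10.0 + np.log(10.0)), 10.0)

    def test_five_kbt_is_about_150(self):
        assert np.isclose(rate_ratio(20.0, 25.0), np.exp(5.0))
        assert 140 < rate_ratio(20.0, 25.0) < 155

    def test_barrier_accessor(self, params):
        fx = generate_fixture("constant_stress_map", params, sigma=1.0)
        prof = pore_energy_profile(fx.payload, params.lambda_rim)
        assert pore_barrier(prof) == (prof.E_pore, prof.rho_c)
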