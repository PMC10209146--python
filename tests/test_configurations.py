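"""Fusion-site configuration building, constraints, and lipid accounting."""

import numpy as np
import pytest

from hemifusion import (CompartmentSpec, MaterialParams, lipid_accounting,
                        build_diaphragm_configuration,
                        build_stalk_configuration, total_energy)
from hemifusion.basis import poly_eval
from hemifusion.configurations import (AxisymStalkProblem, ConfigurationError)
from hemifusion.geometry import monolayer_grids


@pytest.fixture(scope="module")
def ff_stalk(flat, params):
    return build_stalk_configuration(flat, flat, params)


class TestCompartmentSpec:
    def test_flat_implies_tension_reservoir(self):
        c = CompartmentSpec(kind="flat")
        assert c.tension_reservoir and not c.fixed_volume

    def test_curved_requires_radius(self):
        with pytest.raises(ConfigurationError):
            CompartmentSpec(kind="sphere")

    def test_cylinder_requires_length(self):
        with pytest.raises(ConfigurationError):
            CompartmentSpec(kind="cylinder", R_c=20.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            CompartmentSpec(kind="torus", R_c=10.0)

    def test_prefusion_volume(self):
        c = CompartmentSpec(kind="sphere", R_c=20.0)
        assert np.isclose(c.prefusion_volume(), 4 * np.pi * 20.0 ** 3 / 3)


class TestStalkConfiguration:
    def test_unsupported_pairing(self, params):
        cyl = CompartmentSpec(kind="cylinder", R_c=20.0, L=100.0)
        with pytest.raises(ConfigurationError):
            build_stalk_configuration(cyl, cyl, params)

    def test_flat_flat_is_mirror_symmetric(self, ff_stalk):
        assert ff_stalk.problem.mirror
        assert ff_stalk.scalars["rho_size_up"] == ff_stalk.scalars["rho_size_down"]
        assert ff_stalk.scalars["rho_D"] == 0.0

    def test_midplanes_meet_at_ninety_degrees(self, ff_stalk):
        # graph slope of the upper mid-plane at the axis is tan(45°) = 1
        patch = ff_stalk.patches["up"]
        W = float(patch.rho_out_modes[0])
        slope = float(poly_eval(patch.z_modes[0], 0.0, deriv=1)) / W
        assert np.isclose(slope, 1.0, atol=1e-9)

    def test_tilt_vanishes_at_fusion_site_edge(self, ff_stalk, params):
        from hemifusion.minimize import MinimizerOptions, minimize
        res = minimize(ff_stalk, params, MinimizerOptions(n_starts=1,
                                                          max_iter=400))
        for side in ("proximal", "distal"):
            g = monolayer_grids(res.state.patches["up"], side, nx=32,
                                full_output=True, strict=False)
            # tilt at the outermost quadrature node of the relaxed shape
            assert g["t2"][-1, 0] < 1e-3

    def test_edge_curvature_matches_compartment(self, params, sphere20, flat):
        cfg = build_stalk_configuration(sphere20, flat, params)
        patch = cfg.patches["up"]
        rho_s = cfg.scalars["rho_size_up"]
        W = rho_s
        curv = float(poly_eval(patch.z_modes[0], 1.0, deriv=2)) / W ** 2
        R = cfg.scalars["R_eff_up"]
        ct = np.sqrt(1 - (rho_s / R) ** 2)
        assert np.isclose(curv, 1.0 / (R * ct ** 3), atol=1e-3)

    def test_energy_invariant_under_rigid_translation(self, ff_stalk, params):
        bd0 = total_energy(ff_stalk, params)
        bd1 = total_energy(ff_stalk.translated(5.0), params)
        assert np.isclose(bd0.total, bd1.total, atol=1e-9)


class TestVolumeConstraint:
    def test_enclosed_volume_matches_prefusion(self, params, flat):
        sph = CompartmentSpec(kind="sphere", R_c=20.0, fixed_volume=True)
        prob = AxisymStalkProblem(sph, sph, params, regime="before_flipflop")
        vec = prob.initial_vector()
        R_eff = prob._solve_Reff(vec, "up")
        rho_s, _, zc, _, _ = prob._membrane_coeffs(vec, "up", R_eff)
        ct = np.sqrt(1.0 - (rho_s / R_eff) ** 2)
        Vn = prob._near_volume(rho_s, zc)
        Varc = np.pi * R_eff ** 3 * (2 / 3 + ct - ct ** 3 / 3)
        assert abs((Vn + Varc) / sph.prefusion_volume() - 1.0) < 1e-6

    def test_reservoir_compartment_keeps_nominal_radius(self, params):
        sph = CompartmentSpec(kind="sphere", R_c=20.0, fixed_volume=False)
        prob = AxisymStalkProblem(sph, sph, params, regime="reservoir")
        assert prob._solve_Reff(prob.initial_vector(), "up") == 20.0


class TestLipidAccounting:
    def test_reservoir_regime_zeroes_stretching(self, params):
        sph = CompartmentSpec(kind="sphere", R_c=20.0)
        cfg = build_stalk_configuration(sph, sph, params, regime="reservoir")
        bd = total_energy(cfg, params)
        assert sum(bd.stretching.values()) == 0.0
        assert all(v == 0.0 for v in bd.tension.values())

    def test_after_flipflop_zeroes_stretching(self, params):
        sph = CompartmentSpec(kind="sphere", R_c=20.0, fixed_volume=True)
        cfg = build_stalk_configuration(sph, sph, params,
                                        regime="after_flipflop")
        bd = total_energy(cfg, params)
        assert sum(bd.stretching.values()) == 0.0

    def test_before_flipflop_uses_prefusion_areas(self, params):
        sph = CompartmentSpec(kind="sphere", R_c=20.0, fixed_volume=True)
        cfg = build_stalk_configuration(sph, sph, params,
                                        regime="before_flipflop")
        A0 = cfg.units["proximal"]["A0"]
        assert np.isclose(A0, 2 * 4 * np.pi * (20.0 + params.delta0) ** 2)
        assert np.isclose(cfg.units["distal_up"]["A0"],
                          4 * np.pi * (20.0 - params.delta0) ** 2)

    def test_all_reservoir_incompatible_with_before_flipflop(self, params, flat):
        cfg = build_stalk_configuration(flat, flat, params)
        with pytest.raises(ConfigurationError):
            lipid_accounting(cfg, "before_flipflop")

    def test_unknown_regime_rejected(self, params, flat):
        cfg = build_stalk_configuration(flat, flat, params)
        with pytest.raises(ConfigurationError):
            lipid_accounting(cfg, "osmotic")


class TestDiaphragmConfiguration:
    def test_rim_radius_positive_and_free(self, params, flat):
        cfg = build_diaphragm_configuration(flat, flat, params)
        assert cfg.scalars["rho_D"] > 0.0
        assert cfg.scalars["rho_size_up"] > cfg.scalars["rho_D"]

    def test_junction_directors_are_shared(self, params, flat):
        cfg = build_diaphragm_configuration(flat, flat, params)
        dia = cfg.patches["dia"]
        up = cfg.patches["up"]
        psi_dia_rim = float(poly_eval(dia.director_modes["upper"]["psi"][0], 1.0))
        psi_memb_rim = float(poly_eval(up.director_modes["distal"]["psi"][0], 0.0))
        assert np.isclose(psi_dia_rim, psi_memb_rim, atol=1e-9)

    def test_initial_from_stalk_is_energy_continuous(self, params, flat,
                                                     ff_stalk):
        # the inflated-stalk start should cost no more than a few tens of
        # kBT above the stalk configuration it extends
        from hemifusion.minimize import MinimizerOptions, minimize
        rs = minimize(ff_stalk, params, MinimizerOptions(n_starts=1,
                                                         max_iter=400))
        cfg = build_diaphragm_configuration(flat, flat, params,
                                            initial=rs.state)
        # the builder returns a feasible start on the stalk energy scale
        assert cfg.problem.energy(cfg.dof_vector) < 1e5
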