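"""Differential geometry of monolayer dividing planes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemifusion import MaterialParams, tail_length, tilt_vector
from hemifusion.fixtures import generate_fixture
from hemifusion.geometry import (DegenerateDirectorError, GeometryError,
                                 MembranePatch, monolayer_grids,
                                 offset_dividing_plane, splay_and_saddle)


class TestTiltVector:
    def test_aligned_director_has_no_tilt(self):
        n = np.array([0.0, 0.0, 1.0])
        assert np.allclose(tilt_vector(n, n), 0.0)

    def test_direct_evaluation(self):
        t = tilt_vector(np.array([0.6, 0.0, 0.8]), np.array([0.0, 0.0, 1.0]))
        assert np.allclose(t, [0.75, 0.0, 0.0])

    def test_magnitude_is_tangent_of_tilt_angle(self):
        n = np.array([math.sin(math.pi / 4), 0.0, math.cos(math.pi / 4)])
        t = tilt_vector(n, np.array([0.0, 0.0, 1.0]))
        assert np.allclose(t, [1.0, 0.0, 0.0])
        assert np.isclose(np.linalg.norm(t), math.tan(math.pi / 4))

    def test_in_plane_director_rejected(self):
        with pytest.raises(DegenerateDirectorError):
            tilt_vector(np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))

    @settings(max_examples=50, deadline=None)
    @given(theta=st.floats(0.0, 1.2), phi=st.floats(0.0, 6.28))
    def test_orthogonal_to_normal(self, theta, phi):
        N = np.array([0.0, 0.0, 1.0])
        n = np.array([math.sin(theta) * math.cos(phi),
                      math.sin(theta) * math.sin(phi), math.cos(theta)])
        t = tilt_vector(n, N)
        assert abs(t @ N) < 1e-12


class TestTailLength:
    @pytest.mark.parametrize("t, delta0, expected", [
        (np.zeros(3), 1.5, 1.5),
        (np.array([1.0, 0.0, 0.0]), 1.5, 1.5 * math.sqrt(2.0)),
        (np.array([0.75, 0.0, 0.0]), 1.5, 1.875),
    ])
    def test_sqrt_lengthening(self, t, delta0, expected):
        assert np.isclose(tail_length(t, delta0), expected)

    def test_positive_delta0_required(self):
        with pytest.raises(ValueError):
            tail_length(np.zeros(3), 0.0)


class TestSplayAndSaddle:
    def test_flat_patch_reference_state(self, params):
        fx = generate_fixture("flat_patch", params)
        J, K = splay_and_saddle(fx.payload, "upper", (0.5, 0.0))
        assert abs(J) < 1e-10 and abs(K) < 1e-10

    def test_sphere_matches_analytic_curvatures(self, params):
        fx = generate_fixture("analytic_sphere", params, R=20.0)
        for side in ("outer", "inner"):
            g = monolayer_grids(fx.payload, side, nx=32)
            assert np.allclose(g["J"], fx.expected[f"J_{side}"], rtol=1e-6)
            assert np.allclose(g["K"], fx.expected[f"K_{side}"], rtol=1e-6)
            assert g["t2"].max() < 1e-12

    def test_cylinder_matches_analytic_curvatures(self, params):
        fx = generate_fixture("analytic_cylinder", params, R=20.0)
        g = monolayer_grids(fx.payload, "outer", nx=24, nphi=16)
        assert np.allclose(g["J"], fx.expected["J_outer"], rtol=1e-6)
        assert np.abs(g["K"]).max() < 1e-10

    def test_outside_domain_rejected(self, params):
        fx = generate_fixture("flat_patch", params)
        with pytest.raises(GeometryError):
            splay_and_saddle(fx.payload, "upper", (1.5, 0.0))

    def test_tilt_texture_splay_on_flat_midplane(self, params):
        # radial tilt t = a·rho on a flat mid-plane gives J -> 2a on axis
        a = 0.02
        rho_out = 5.0
        # director angle psi = pi/2 - atan(a*rho): fit as polynomial
        from hemifusion.basis import ConstrainedPoly
        poly = ConstrainedPoly(8, [])
        y = poly.fit(lambda x: math.pi / 2 - math.atan(a * rho_out * x))
        patch = MembranePatch(
            symmetry_class="axisymmetric", order=8,
            rho_in_modes={0: 0.0}, rho_out_modes={0: rho_out},
            z_modes={0: np.zeros(9)},
            director_modes={"upper": {"psi": {0: poly.coeffs(y)}}},
            delta0=params.delta0)
        g = monolayer_grids(patch, "upper", nx=40)
        # inner node J approaches 2a as rho -> 0
        assert abs(g["J"][0, 0] - 2.0 * a) < 0.1 * 2.0 * a


class TestOffsetDividingPlane:
    def test_flat_offset_planes(self, params):
        fx = generate_fixture("flat_patch", params)
        frames = offset_dividing_plane(fx.payload, "upper", nx=8)
        zs = np.array([f.position[2] for f in frames])
        assert np.allclose(zs, params.delta0)

    def test_sphere_offsets_are_concentric(self, params):
        fx = generate_fixture("analytic_sphere", params, R=20.0)
        for side, Rd in (("outer", 21.5), ("inner", 18.5)):
            frames = offset_dividing_plane(fx.payload, side, nx=8)
            radii = np.array([np.linalg.norm(f.position) for f in frames])
            assert np.allclose(radii, Rd, atol=1e-8)

    def test_small_sphere_inward_offset_self_intersects(self, params):
        fx = generate_fixture("analytic_sphere", params, R=1.0, rho_out=0.8)
        with pytest.raises(GeometryError):
            offset_dividing_plane(fx.payload, "inner", nx=8)


class TestInvariances:
    def test_area_converges_with_quadrature_order(self, params):
        fx = generate_fixture("analytic_sphere", params, R=20.0)
        a1 = monolayer_grids(fx.payload, "outer", nx=24)["area"]
        a2 = monolayer_grids(fx.payload, "outer", nx=48)["area"]
        assert abs(a2 / a1 - 1.0) < 1e-8

    def test_rigid_translation_leaves_geometry_unchanged(self, params):
        fx = generate_fixture("analytic_sphere", params, R=20.0)
        g0 = monolayer_grids(fx.payload, "outer", nx=16)
        import copy
        moved = copy.copy(fx.payload)
        zbg = fx.payload.z_background
        moved.z_background = lambda rho, phi: zbg(rho, phi) + 11.0
        g1 = monolayer_grids(moved, "outer", nx=16)
        for key in ("J", "K", "t2", "dA"):
            assert np.allclose(g0[key], g1[key], atol=1e-10)
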