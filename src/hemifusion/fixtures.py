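"""Analytic fixtures: test surfaces and synthetic stress maps with
closed-form expected values.

These provide solver-independent oracles: sphere and cylinder patches whose
bending energies have closed forms, flat reference patches, and synthetic
stress maps whose pore barriers are known analytically (constant σ gives
E_pore = πλ²/σ at ρ_c = λ/σ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elastic import MaterialParams
from .geometry import MembranePatch
from .pore import StressMap

__all__ = ["Fixture", "generate_fixture"]

KINDS = ("analytic_sphere", "analytic_cylinder", "flat_patch",
         "constant_stress_map", "radial_stress_map")


@dataclass
class Fixture:
    kind: str
    parameters: dict
    payload: object                      # MembranePatch or StressMap
    expected: dict = field(default_factory=dict)


def _sphere_patch(R: float, delta0: float, rho_out: float) -> MembranePatch:
    def z_bg(rho, phi):
        return -np.sqrt(np.maximum(R * R - rho * rho, 1e-12))

    def normal(sign):
        def f(rho, phi):
            zero = np.zeros_like(np.asarray(rho, dtype=float))
            return (sign * rho / R, zero,
                    -sign * np.sqrt(np.maximum(R * R - rho * rho, 1e-12)) / R)
        return f

    return MembranePatch(
        symmetry_class="axisymmetric", order=2,
        rho_in_modes={0: 0.0}, rho_out_modes={0: rho_out},
        z_modes={}, director_modes={"outer": {}, "inner": {}},
        z_background=z_bg,
        director_background={"outer": normal(+1), "inner": normal(-1)},
        delta0=delta0)


def generate_fixture(kind: str, params: MaterialParams | None = None,
                     **kw) -> Fixture:
    """Build an analytic fixture with its closed-form expected values."""
    params = params or MaterialParams()
    if kind == "analytic_sphere":
        R = kw.get("R", 20.0)
        rho_out = kw.get("rho_out", 0.45 * R)
        patch = _sphere_patch(R, params.delta0, rho_out)
        U0 = (16.0 * np.pi * params.kappa_m * (1.0 - params.delta0 * params.J_sm)
              + 8.0 * np.pi * params.kappa_bar)
        expected = {
            "J_outer": 2.0 / (R + params.delta0),
            "J_inner": -2.0 / (R - params.delta0),
            "K_outer": 1.0 / (R + params.delta0) ** 2,
            "K_inner": 1.0 / (R - params.delta0) ** 2,
            "U0_full_sphere": float(U0),
        }
        return Fixture(kind, {"R": R, "rho_out": rho_out}, patch, expected)

    if kind == "analytic_cylinder":
        from .configurations import cylinder_patch
        R = kw.get("R", 20.0)
        L = kw.get("L", 100.0)
        rho_out = kw.get("rho_out", 0.4 * R)
        patch = cylinder_patch(R, 0.0, rho_out, params.delta0)
        U0 = 2.0 * np.pi * params.kappa_m * R * L / (R ** 2 - params.delta0 ** 2)
        expected = {
            "J_outer": 1.0 / (R + params.delta0),
            "J_inner": -1.0 / (R - params.delta0),
            "K": 0.0,
            "U0_cylinder": float(U0),
        }
        return Fixture(kind, {"R": R, "L": L, "rho_out": rho_out}, patch, expected)

    if kind == "flat_patch":
        rho_out = kw.get("rho_out", 10.0)
        patch = MembranePatch(
            symmetry_class="axisymmetric", order=2,
            rho_in_modes={0: 0.0}, rho_out_modes={0: rho_out},
            z_modes={0: np.zeros(3)},
            director_modes={"upper": {"psi": {0: np.array([np.pi / 2])}},
                            "lower": {"psi": {0: np.array([-np.pi / 2])}}},
            delta0=params.delta0)
        return Fixture(kind, {"rho_out": rho_out}, patch,
                       {"energy": 0.0, "J": 0.0, "K": 0.0, "tilt": 0.0})

    if kind == "constant_stress_map":
        sigma = kw.get("sigma", 1.0)
        rim = kw.get("rim", 10.0)
        n = kw.get("n", 101)
        smap = StressMap(rho=np.linspace(0.0, rim, n), phi=np.array([0.0]),
                         sigma=np.full((n, 1), float(sigma)), u0=0.0,
                         rim_radius=np.array([rim]))
        lam = params.lambda_rim
        expected = {}
        if sigma > 0:
            expected = {"E_pore": float(np.pi * lam ** 2 / sigma),
                        "rho_c": float(lam / sigma)}
        return Fixture(kind, {"sigma": sigma, "rim": rim}, smap, expected)

    if kind == "radial_stress_map":
        # σ(ρ) = s0 + s1·ρ gives U = 2πρλ − π s0 ρ² − (2π/3) s1 ρ³
        s0 = kw.get("s0", 0.5)
        s1 = kw.get("s1", 0.2)
        rim = kw.get("rim", 10.0)
        n = kw.get("n", 201)
        rho = np.linspace(0.0, rim, n)
        smap = StressMap(rho=rho, phi=np.array([0.0]),
                         sigma=(s0 + s1 * rho)[:, None], u0=0.0,
                         rim_radius=np.array([rim]))
        lam = params.lambda_rim

        def U(r):
            return (2.0 * np.pi * r * lam - np.pi * s0 * r ** 2
                    - 2.0 * np.pi / 3.0 * s1 * r ** 3)
        rg = np.linspace(0, rim, 20001)
        Ug = U(rg)
        expected = {"E_pore": float(Ug.max()), "rho_c": float(rg[Ug.argmax()])}
        return Fixture(kind, {"s0": s0, "s1": s1, "rim": rim}, smap, expected)

    raise ValueError(f"unsupported fixture kind {kind!r}; choose from {KINDS}")
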