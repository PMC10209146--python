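"""Fusion-pore energetics on the hemifusion diaphragm.

The stress difference between the diaphragm and the surrounding compartment
membranes,

    σ(ρ, φ) = u₊(ρ, φ) + u₋(ρ, φ) − 2 u₀,

drives pore expansion (u± are the tilt-splay energy densities of the two
diaphragm monolayers including their local tension; u₀ is the relaxed
density of the surrounding compartment membranes).  A pore of radius ρ at
the diaphragm centre costs rim energy 2πρλ and releases the integrated
stress:

    U_pore(ρ) = 2πρλ − ∫₀^ρ∫₀^{2π} σ(ρ', φ) ρ' dρ' dφ.

The barrier E_pore is the maximum of U_pore; with constant σ the profile
has the closed form 2πρλ − πρ²σ, critical radius ρ_c = λ/σ and barrier
πλ²/σ.  The Arrhenius mean pore-opening time is τ = C exp(E_pore/k_BT)
with unknown prefactor C, so only rate *ratios* are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elastic import MaterialParams
from .geometry import monolayer_grids

__all__ = ["StressMap", "PoreProfile", "stress_map", "pore_energy_profile",
           "pore_barrier", "rate_ratio", "NoDiaphragmError"]


class NoDiaphragmError(ValueError):
    """Pore energetics require a converged diaphragm state (ρ_D > 0)."""


@dataclass
class StressMap:
    """Stress difference σ on the diaphragm, sampled on a (ρ, φ) grid."""

    rho: np.ndarray          # (n_rho,) radial samples of the grid rays (nm)
    phi: np.ndarray          # (n_phi,) azimuthal samples (rad)
    sigma: np.ndarray        # (n_rho, n_phi) σ values (k_BT/nm²)
    u0: float                # surrounding-compartment density (k_BT/nm²)
    rim_radius: np.ndarray   # (n_phi,) rim radius per azimuth (nm)

    @property
    def axisymmetric(self) -> bool:
        return self.sigma.shape[1] == 1

    def to_frame(self):
        import pandas as pd
        rows = []
        for j, p in enumerate(self.phi):
            for i, r in enumerate(self.rho[:, j] if self.rho.ndim > 1 else self.rho):
                rows.append({"rho_nm": r, "phi_rad": p,
                             "sigma_kBT_nm2": self.sigma[i, j]})
        return pd.DataFrame(rows)


@dataclass
class PoreProfile:
    """Pore-opening energy profile U_pore(ρ)."""

    rho: np.ndarray          # radius grid (nm)
    U: np.ndarray            # U_pore (k_BT)
    E_pore: float            # barrier (k_BT)
    rho_c: float             # critical radius (nm)
    rim_limited: bool        # maximum at the diaphragm rim, not interior
    lambda_rim: float        # line tension used (k_BT/nm)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"rho_nm": self.rho, "U_pore_kBT": self.U})


def _surrounding_density(state, params: MaterialParams, tensions: dict) -> float:
    """Mean monolayer density u0 of the undisturbed compartment membranes,
    including their current tension (zero for flat reservoirs)."""
    dens = []
    for m, comp in zip(("up", "down"), state.compartments):
        if comp is None or comp.kind == "flat":
            dens.append(0.0)
            continue
        prox_unit = "proximal"
        dist_unit = f"distal_{m}" if f"distal_{m}" in state.units else "distal_up"
        rec = None
        for far in state.far:
            # far-field records carry the analytic compartment densities
            if hasattr(far, "monolayer_density"):
                rec = far
                break
        if rec is None:
            dens.append(0.0)
            continue
        u_out = rec.monolayer_density(+1, params) + tensions.get(prox_unit, 0.0)
        u_in = rec.monolayer_density(-1, params) + tensions.get(dist_unit, 0.0)
        dens.append(0.5 * (u_out + u_in))
    return 0.5 * sum(dens)


def stress_map(result, params: MaterialParams, nx: int = 200,
               nphi: int | None = None) -> StressMap:
    """Stress difference σ = u₊ + u₋ − 2u₀ on a converged diaphragm.

    ``result`` is an :class:`~hemifusion.minimize.EquilibriumResult` whose
    state contains a diaphragm element; the densities include the local
    tension γ of each leaflet's accounting unit.
    """
    state = getattr(result, "state", result)
    bd = getattr(result, "breakdown", None)
    if "dia" not in state.patches:
        raise NoDiaphragmError("state has no diaphragm element (stalk, ρ_D = 0)")
    dia = state.patches["dia"]
    tensions = dict(bd.tension) if bd is not None else {}

    mirror = "lower" not in dia.director_modes
    sides = [("upper", "distal_up")]
    sides.append(("upper", "distal_up") if mirror else ("lower", "distal_down"))

    u_sum = None
    for side, unit in sides:
        g = monolayer_grids(dia, side, nx=nx, nphi=nphi, strict=False)
        u = (0.5 * params.kappa_m * g["J"] ** 2
             - params.kappa_m * g["J"] * params.J_sm
             + params.kappa_bar * g["K"]
             + 0.5 * params.kappa_t * g["t2"]
             + tensions.get(unit, 0.0))
        u_sum = u if u_sum is None else u_sum + u
        xg, phig = g["x"], g["phi"]
    # the collocation derivative of the axis-regular fields is noisy on the
    # innermost sliver (J carries n_ρ/ρ terms); it is measure-negligible in
    # the energy and excluded from the sampled stress map
    keep = xg > 0.02
    xg = xg[keep]
    u_sum = u_sum[keep]

    u0 = _surrounding_density(state, params, tensions)
    phi = np.asarray(phig)
    rim = np.array([float(sum(v * np.cos(k * p) for k, v in dia.rho_out_modes.items()))
                    for p in phi])
    rho = np.outer(xg, rim)
    sigma = u_sum - 2.0 * u0
    return StressMap(rho=rho, phi=phi, sigma=sigma, u0=u0, rim_radius=rim)


def pore_energy_profile(smap: StressMap, lambda_rim: float,
                        n_rho: int = 400) -> PoreProfile:
    """Pore-opening energy U_pore(ρ) from the stress map (Gauss data is
    interpolated onto a uniform radial grid per azimuthal ray; the pore is
    centred at the diaphragm centre)."""
    if lambda_rim < 0:
        raise ValueError("line tension must be non-negative")
    rho_max = float(np.min(smap.rim_radius))
    rho_grid = np.linspace(0.0, rho_max, n_rho)
    nphi = smap.phi.size
    # cumulative stress integral, one azimuthal ray at a time
    dphi = 2.0 * np.pi / nphi
    integrand = np.zeros_like(rho_grid)
    for j in range(nphi):
        r_nodes = smap.rho[:, j] if smap.rho.ndim > 1 else smap.rho
        s = np.interp(rho_grid, r_nodes, smap.sigma[:, j],
                      left=smap.sigma[0, j], right=smap.sigma[-1, j])
        integrand += s * rho_grid * dphi
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (integrand[1:] + integrand[:-1]) * np.diff(rho_grid))])
    U = 2.0 * np.pi * rho_grid * lambda_rim - cum
    imax = int(np.argmax(U))
    rim_limited = imax >= n_rho - 2
    E_pore, rho_c = _refine_max(rho_grid, U, imax)
    return PoreProfile(rho=rho_grid, U=U, E_pore=E_pore, rho_c=rho_c,
                       rim_limited=rim_limited, lambda_rim=lambda_rim)


def _refine_max(x, y, i):
    """Quadratic refinement of a grid maximum."""
    if 0 < i < len(x) - 1:
        x0, x1, x2 = x[i - 1], x[i], x[i + 1]
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = (y0 - 2 * y1 + y2)
        if abs(denom) > 1e-300:
            dx = 0.5 * (y0 - y2) / denom * (x1 - x0)
            xm = x1 + dx
            ym = y1 - 0.25 * (y0 - y2) * dx / (x1 - x0)
            return float(ym), float(xm)
    return float(y[i]), float(x[i])


def pore_barrier(profile: PoreProfile) -> tuple[float, float]:
    """Barrier E_pore (k_BT) and critical radius ρ_c (nm)."""
    return profile.E_pore, profile.rho_c


def rate_ratio(E_pore_a: float, E_pore_b: float) -> float:
    """Arrhenius pore-opening rate ratio k_a/k_b = exp(E_b − E_a); the
    unknown attempt-frequency prefactor cancels."""
    return float(np.exp(E_pore_b - E_pore_a))
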