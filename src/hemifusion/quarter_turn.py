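"""Quarter-turn symmetric fusion sites (cylinder-flat pairing).

Fusion between a long cylindrical membrane (axis along x̂, radius R_c,
lying above) and a flat membrane is not axisymmetric: fields carry
low-order Fourier modes on top of the axisymmetric profiles.  Mid-planes
are the analytic cylinder graph plus polynomial deviations w₀(x) +
w₂(x)cos 2φ; directors use the same in-plane angle representation as the
axisymmetric solver, ψ(x,φ) = ψ₀(x) + ψ₂(x)cos 2φ, plus an azimuthal
component p(x,φ) = q₂(x)sin 2φ (directors are (cos ψ, p, sin ψ)
normalized, so they are near-unit by construction).  The truncation at the
cos 2φ mode leaves only O((ρ sin φ/R)³) residual tilt at the fusion-site
edge, negligible at the radii of interest; the measured rim ellipticity of
the diaphragm is likewise sub-nm, which justifies the truncation.

Long tubes are laterally connected to large membrane reservoirs, so no
stretching energy or volume constraint applies; the tube length L only
enters through the prefusion reference and cancels from the barriers.
"""

from __future__ import annotations

import math

import numpy as np

from .basis import ConstrainedPoly, gauss_nodes, poly_eval
from .configurations import (CompartmentSpec, ConfigurationError,
                             CylinderFarField, FusionSiteState, _DofMap,
                             lipid_accounting)
from .elastic import MaterialParams, total_energy
from .geometry import GeometryError, MembranePatch

__all__ = ["QuarterTurnStalkProblem", "QuarterTurnDiaphragmProblem"]

NPHI = 16


def _canonical(up: CompartmentSpec, down: CompartmentSpec):
    if (up.kind, down.kind) == ("flat", "cylinder"):
        up, down = down, up
    if (up.kind, down.kind) != ("cylinder", "flat"):
        raise ConfigurationError(
            "quarter-turn solver supports the cylinder-flat pairing only")
    return up, down


def _mode_project(values, phi, trig, k):
    """Least-squares amplitude of trig(kφ) in a sampled φ-profile (mean
    for k = 0)."""
    values = np.asarray(values, dtype=float)
    if k == 0:
        return float(values.mean())
    b = trig(k * phi)
    return float(values @ b / max(b @ b, 1e-300))


def _fit(poly: ConstrainedPoly, xg, values, cons_vals):
    """Least-squares free coefficients reproducing nodal values under the
    given constraint values."""
    from .basis import cheb_vander
    B = cheb_vander(np.asarray(xg), poly.order)
    base = poly._Cpinv @ np.asarray(cons_vals, dtype=float) \
        if len(poly.constraints) else np.zeros(poly.order + 1)
    target = np.asarray(values, dtype=float) - B @ base
    y, *_ = np.linalg.lstsq(B @ poly.N, target, rcond=None)
    return y


class _QuarterTurnBase:
    """Cylinder background fields and their angle-mode projections."""

    def __init__(self, up, down, params: MaterialParams, regime: str,
                 order: int = 8, mode2_order: int = 4, nx: int = 22):
        up, down = _canonical(up, down)
        if up.R_c <= params.delta0:
            raise ConfigurationError("R_c must exceed the tail length delta0")
        self.up, self.down = up, down
        self.params = params
        self.regime = regime
        self.order = order
        self.mode2_order = mode2_order
        self.nx = nx
        self.L = up.L
        self.mirror = False
        self._phi = np.arange(NPHI) * 2.0 * np.pi / NPHI

    def _bg_z(self, z_c):
        R = self.up.R_c

        def f(rho, phi):
            y = rho * np.sin(phi)
            return z_c - np.sqrt(np.maximum(R * R - y * y, 1e-12))
        return f

    def _cyl_normal_angles(self, rho, sign):
        """(ψ, p) of the cylinder normal at chart radius rho over the φ
        grid: ψ is the in-plane director angle, p the azimuthal component
        in the angle representation."""
        R = self.up.R_c
        y = rho * np.sin(self._phi)
        sb = y / R
        cb = np.sqrt(np.maximum(1.0 - sb * sb, 0.0))
        a = sign * sb * np.sin(self._phi)        # ρ̂ component
        b = sign * sb * np.cos(self._phi)        # φ̂ component
        c = -sign * cb                           # ẑ component
        base = -math.pi / 2 if sign > 0 else math.pi / 2
        psi = np.arctan2(c, a)
        # unwrap around the base angle so the mode fit is smooth
        psi = base + np.arctan2(np.sin(psi - base), np.cos(psi - base))
        p = b / np.maximum(np.sqrt(a * a + c * c), 1e-12)
        return psi, p

    def _bg_angle_modes(self, rho, sign, upper=True):
        """Mode amplitudes (ψ₀, ψ₂, q₂) and their dρ-derivatives of the
        compartment normal at chart radius rho."""
        if not upper:
            base = math.pi / 2 * (1 if sign > 0 else -1)
            return {"psi0": base, "psi2": 0.0, "q2": 0.0,
                    "dpsi0": 0.0, "dpsi2": 0.0, "dq2": 0.0}
        h = 1e-4 * max(rho, 1.0)
        out = {}
        for tag, r in (("", rho), ("+", rho + h), ("-", max(rho - h, 0.0))):
            psi, p = self._cyl_normal_angles(r, sign)
            out[tag] = (_mode_project(psi, self._phi, np.cos, 0),
                        _mode_project(psi, self._phi, np.cos, 2),
                        _mode_project(p, self._phi, np.sin, 2))
        v, vp, vm = out[""], out["+"], out["-"]
        return {"psi0": v[0], "psi2": v[1], "q2": v[2],
                "dpsi0": (vp[0] - vm[0]) / (2 * h),
                "dpsi2": (vp[1] - vm[1]) / (2 * h),
                "dq2": (vp[2] - vm[2]) / (2 * h)}


class QuarterTurnStalkProblem(_QuarterTurnBase):
    """Hemifusion stalk between a cylinder (above) and a flat membrane."""

    kind = "stalk"

    def __init__(self, up, down, params, regime: str = "reservoir",
                 order: int = 8, mode2_order: int = 4, nx: int = 22):
        super().__init__(up, down, params, regime, order, mode2_order, nx)
        M, M2 = self.order, self.mode2_order
        # mid-plane deviations: centre value+slope, edge C²
        self.W0 = ConstrainedPoly(M, [(0.0, 0), (0.0, 1),
                                      (1.0, 0), (1.0, 1), (1.0, 2)])
        self.W2 = ConstrainedPoly(M2 + 2, [(0.0, 0), (0.0, 1),
                                           (1.0, 0), (1.0, 1), (1.0, 2)])
        # director angle profiles: centre value, edge value+slope (mode 0)
        self.P0 = ConstrainedPoly(M, [(0.0, 0), (1.0, 0), (1.0, 1)])
        self.P2 = ConstrainedPoly(M2, [(0.0, 0), (1.0, 0)])
        self.Q2 = ConstrainedPoly(M2, [(0.0, 0), (1.0, 0)])

        dm = _DofMap()
        for m in ("up", "down"):
            dm.add(f"w0_{m}", self.W0.n_free)
            dm.add(f"w2_{m}", self.W2.n_free)
            for leaf in ("p", "d"):
                dm.add(f"psi0_{leaf}_{m}", self.P0.n_free)
                dm.add(f"psi2_{leaf}_{m}", self.P2.n_free)
                dm.add(f"q2_{leaf}_{m}", self.Q2.n_free)
            dm.add(f"rho_size_{m}", 1, 3.5,
                   min(12.0, 0.6 * self.up.R_c) if m == "up" else 12.0)
        dm.add("z_edge_down", 1, -14.0, -0.3)
        dm.add("z_c_off", 1, 0.0, 10.0)
        dm.add("alpha", 1, 0.55, 1.02)
        dm.add("psi_c", 1, -0.7, 0.7)
        self.dofs = dm

    def assemble(self, vec) -> FusionSiteState:
        vec = np.asarray(vec, dtype=float)
        params = self.params
        R = self.up.R_c
        alpha = float(self.dofs.get(vec, "alpha"))
        psi_c = float(self.dofs.get(vec, "psi_c"))
        z_ed = float(self.dofs.get(vec, "z_edge_down"))
        z_c = R + float(self.dofs.get(vec, "z_c_off"))

        patches, monolayers = {}, []
        for m in ("up", "down"):
            upper = (m == "up")
            rho_s = float(self.dofs.get(vec, f"rho_size_{m}"))
            W = rho_s
            slope_c = math.tan(alpha) if upper else math.tan(alpha - math.pi / 2)
            if upper:
                w0_vals = [R - z_c, W * slope_c, 0.0, 0.0, 0.0]
                z_bg = self._bg_z(z_c)
            else:
                w0_vals = [0.0, W * slope_c, z_ed, 0.0, 0.0]
                z_bg = None
            w0 = self.W0.coeffs(self.dofs.get(vec, f"w0_{m}"), w0_vals)
            w2 = self.W2.coeffs(self.dofs.get(vec, f"w2_{m}"), [0.0] * 5)
            dmodes = {}
            for leaf, sign in (("proximal", +1), ("distal", -1)):
                tag = "p" if leaf == "proximal" else "d"
                bg = self._bg_angle_modes(rho_s, sign, upper)
                if leaf == "proximal":
                    c0 = psi_c
                else:
                    c0 = math.pi / 2 if upper else -math.pi / 2
                p0 = self.P0.coeffs(self.dofs.get(vec, f"psi0_{tag}_{m}"),
                                    [c0, bg["psi0"], W * bg["dpsi0"]])
                p2 = self.P2.coeffs(self.dofs.get(vec, f"psi2_{tag}_{m}"),
                                    [0.0, bg["psi2"]])
                q2 = self.Q2.coeffs(self.dofs.get(vec, f"q2_{tag}_{m}"),
                                    [0.0, bg["q2"]])
                dmodes[leaf] = {"psi": {0: p0, 2: p2}, "p": {2: q2}}
            patch = MembranePatch(
                symmetry_class="quarter_turn", order=self.order,
                rho_in_modes={0: 0.0}, rho_out_modes={0: rho_s},
                z_modes={0: w0, 2: w2}, director_modes=dmodes,
                z_background=z_bg, delta0=params.delta0)
            patches[m] = patch
            dist_unit = "distal_up" if upper else "distal_down"
            monolayers.append(dict(patch=patch, side="proximal", unit="proximal",
                                   label=f"{m}.proximal", mult=1, area_mult=1))
            monolayers.append(dict(patch=patch, side="distal", unit=dist_unit,
                                   label=f"{m}.distal", mult=1, area_mult=1))

        far = [CylinderFarField(
            R=R, L=self.L, rho_fp=float(self.dofs.get(vec, "rho_size_up")),
            z_c=z_c, leaflets=[(+1, "proximal", 1, 1),
                               (-1, "distal_up", 1, 1)])]
        units = {"proximal": {"A0": None, "reservoir": True},
                 "distal_up": {"A0": None, "reservoir": True},
                 "distal_down": {"A0": None, "reservoir": True}}
        scalars = {"rho_D": 0.0,
                   "rho_size_up": float(self.dofs.get(vec, "rho_size_up")),
                   "rho_size_down": float(self.dofs.get(vec, "rho_size_down")),
                   "h": -z_ed + (z_c - R), "z_c": z_c, "alpha": alpha}
        junctions = [{"a": ("up.proximal", 0), "b": ("down.proximal", 0)}]
        state = FusionSiteState(
            patches=patches, monolayers=monolayers, units=units, far=far,
            scalars=scalars, compartments=(self.up, self.down),
            symmetry_class="quarter_turn", nx=self.nx, nphi=NPHI,
            problem=self, dof_vector=vec.copy(), junctions=junctions)
        state.junction_mu = getattr(self, "junction_mu", 100.0)
        lipid_accounting(state, self.regime)
        return state

    def energy(self, vec, params: MaterialParams | None = None) -> float:
        params = params or self.params
        try:
            state = self.assemble(vec)
            bd = total_energy(state, params, nx=self.nx, nphi=NPHI)
        except GeometryError as e:
            return 1e6 * (1.0 + e.badness)
        except (ValueError, ZeroDivisionError):
            return 2e7
        if not np.isfinite(bd.total):
            return 2e7
        return bd.total

    def bounds(self):
        return self.dofs.bounds()

    def initial_from_axisym(self, ff_state: FusionSiteState) -> np.ndarray:
        """Compose the start from a converged axisymmetric flat-flat stalk;
        the cylinder's azimuthal structure enters through the background
        and the mode-2 boundary values."""
        vec = self.initial_vector()
        src = ff_state.patches["up"]
        rho_s = min(float(src.rho_out_modes[0]),
                    self.dofs.bound("rho_size_up")[1] - 1e-9)
        z_e = float(poly_eval(src.z_modes[0], 1.0))
        self.dofs.set(vec, "rho_size_up", rho_s)
        self.dofs.set(vec, "rho_size_down", rho_s)
        self.dofs.set(vec, "z_c_off", min(10.0, z_e))
        self.dofs.set(vec, "z_edge_down", -z_e)
        z_c = self.up.R_c + min(10.0, z_e)
        xg, _ = gauss_nodes(48)
        for m in ("up", "down"):
            upper = (m == "up")
            sgn = 1.0 if upper else -1.0
            W = float(self.dofs.get(vec, f"rho_size_{m}"))
            xs = np.minimum(1.0, W * xg / float(src.rho_out_modes[0]))
            zsrc = sgn * poly_eval(src.z_modes[0], xs)
            if upper:
                zbg0 = np.array([_mode_project(np.asarray(
                    self._bg_z(z_c)(W * x, self._phi)), self._phi, np.cos, 0)
                    for x in xg])
                # deviation target blends to the pure cylinder at the edge
                prof0 = (zsrc - zbg0) * (1.0 - xg ** 2) ** 2
                w0_vals = [self.up.R_c - z_c, W, 0.0, 0.0, 0.0]
                prof2 = np.array([-_mode_project(np.asarray(
                    self._bg_z(z_c)(W * x, self._phi)), self._phi, np.cos, 2)
                    for x in xg]) * (1.0 - xg) ** 3
            else:
                prof0 = zsrc
                w0_vals = [0.0, -W, -z_e, 0.0, 0.0]
                prof2 = np.zeros_like(xg)
            self.dofs.set(vec, f"w0_{m}", _fit(self.W0, xg, prof0, w0_vals))
            self.dofs.set(vec, f"w2_{m}", _fit(self.W2, xg, prof2, [0.0] * 5))
            for leaf, sign in (("proximal", +1), ("distal", -1)):
                tag = "p" if leaf == "proximal" else "d"
                psis = sgn * poly_eval(src.director_modes[leaf]["psi"][0], xs)
                bg = self._bg_angle_modes(W, sign, upper)
                c0 = 0.0 if leaf == "proximal" else sgn * math.pi / 2
                self.dofs.set(vec, f"psi0_{tag}_{m}", _fit(
                    self.P0, xg, psis, [c0, bg["psi0"], W * bg["dpsi0"]]))
                if upper:
                    prof2 = np.array([self._bg_angle_modes(
                        W * x, sign, True)["psi2"] for x in xg])
                    profq = np.array([self._bg_angle_modes(
                        W * x, sign, True)["q2"] for x in xg])
                else:
                    prof2 = profq = np.zeros_like(xg)
                self.dofs.set(vec, f"psi2_{tag}_{m}", _fit(
                    self.P2, xg, prof2, [0.0, bg["psi2"]]))
                self.dofs.set(vec, f"q2_{tag}_{m}", _fit(
                    self.Q2, xg, profq, [0.0, bg["q2"]]))
        self.dofs.set(vec, "alpha", math.pi / 4)
        self.dofs.set(vec, "psi_c", 0.0)
        return vec

    def initial_vector(self) -> np.ndarray:
        vec = np.zeros(self.dofs.n)
        self.dofs.set(vec, "rho_size_up", 8.0)
        self.dofs.set(vec, "rho_size_down", 8.0)
        self.dofs.set(vec, "z_edge_down", -3.0)
        self.dofs.set(vec, "z_c_off", 3.0)
        self.dofs.set(vec, "alpha", math.pi / 4)
        self.dofs.set(vec, "psi_c", 0.0)
        return vec


class QuarterTurnDiaphragmProblem(_QuarterTurnBase):
    """Hemifusion diaphragm between cylinder and flat (elliptical rim)."""

    kind = "diaphragm"

    def __init__(self, up, down, params, regime: str = "reservoir",
                 order: int = 8, mode2_order: int = 4, nx: int = 22):
        super().__init__(up, down, params, regime, order, mode2_order, nx)
        M, M2 = self.order, self.mode2_order
        self.W0 = ConstrainedPoly(M, [(0.0, 0), (1.0, 0), (1.0, 1), (1.0, 2)])
        self.W2 = ConstrainedPoly(M2 + 2, [(0.0, 0), (1.0, 0), (1.0, 1),
                                           (1.0, 2)])
        self.P0 = ConstrainedPoly(M, [(0.0, 0), (1.0, 0), (1.0, 1)])
        self.P2 = ConstrainedPoly(M2, [(0.0, 0), (1.0, 0)])
        self.Q2 = ConstrainedPoly(M2, [(0.0, 0), (1.0, 0)])
        # diaphragm: centre-regular mid-plane and angle fields
        self.Zd0 = ConstrainedPoly(M, [(0.0, 0), (0.0, 1), (1.0, 0)])
        self.Zd2 = ConstrainedPoly(M2 + 2, [(0.0, 0), (0.0, 1), (1.0, 0)])
        self.Pd0 = ConstrainedPoly(M, [(0.0, 0), (1.0, 0)])
        self.Pd2 = ConstrainedPoly(M2, [(0.0, 0), (1.0, 0)])
        self.Qd2 = ConstrainedPoly(M2, [(0.0, 0), (1.0, 0)])

        dm = _DofMap()
        dm.add("rho_D", 1, 0.8, 8.0)
        dm.add("rho_D2", 1, -1.5, 1.5)      # cos 2φ rim anisotropy
        dm.add("z_rim", 1, -5.0, 5.0)
        dm.add("z_rim2", 1, -2.0, 2.0)
        # shared junction directors (angle modes)
        dm.add("psi_rim_p", 1, -1.3, 1.3)
        dm.add("psi_rim_p2", 1, -0.6, 0.6)
        dm.add("q_rim_p2", 1, -0.6, 0.6)
        dm.add("psi_rim_d_up", 1, 0.5, 2.6)
        dm.add("psi_rim_d_up2", 1, -0.6, 0.6)
        dm.add("q_rim_d_up2", 1, -0.6, 0.6)
        dm.add("psi_rim_d_down", 1, -2.6, -0.5)
        dm.add("psi_rim_d_down2", 1, -0.6, 0.6)
        dm.add("q_rim_d_down2", 1, -0.6, 0.6)
        for pre in ("du", "dl"):            # diaphragm upper/lower leaflets
            dm.add(f"psi0_{pre}", self.Pd0.n_free)
            dm.add(f"psi2_{pre}", self.Pd2.n_free)
            dm.add(f"q2_{pre}", self.Qd2.n_free)
        dm.add("zd0", self.Zd0.n_free)
        dm.add("zd2", self.Zd2.n_free)
        for m in ("up", "down"):
            dm.add(f"w0_{m}", self.W0.n_free)
            dm.add(f"w2_{m}", self.W2.n_free)
            for leaf in ("p", "d"):
                dm.add(f"psi0_{leaf}_{m}", self.P0.n_free)
                dm.add(f"psi2_{leaf}_{m}", self.P2.n_free)
                dm.add(f"q2_{leaf}_{m}", self.Q2.n_free)
            dm.add(f"W_{m}", 1, 3.5, 8.0)
        dm.add("z_edge_down", 1, -14.0, -0.3)
        dm.add("z_c_off", 1, 0.0, 10.0)
        self.dofs = dm

    def _rim(self, vec):
        d0 = float(self.dofs.get(vec, "rho_D"))
        d2 = float(self.dofs.get(vec, "rho_D2"))
        if d0 - abs(d2) < 0.5:
            raise GeometryError("rim radius too small or too elliptical")
        return d0, d2

    def assemble(self, vec) -> FusionSiteState:
        vec = np.asarray(vec, dtype=float)
        params = self.params
        R = self.up.R_c
        d0, d2 = self._rim(vec)
        z_rim = float(self.dofs.get(vec, "z_rim"))
        z_rim2 = float(self.dofs.get(vec, "z_rim2"))
        z_ed = float(self.dofs.get(vec, "z_edge_down"))
        z_c = R + float(self.dofs.get(vec, "z_c_off"))
        rim_of_phi = d0 + d2 * np.cos(2.0 * self._phi)

        rimvals = {
            ("proximal", "up"): (float(self.dofs.get(vec, "psi_rim_p")),
                                 float(self.dofs.get(vec, "psi_rim_p2")),
                                 float(self.dofs.get(vec, "q_rim_p2"))),
            ("distal", "up"): (float(self.dofs.get(vec, "psi_rim_d_up")),
                               float(self.dofs.get(vec, "psi_rim_d_up2")),
                               float(self.dofs.get(vec, "q_rim_d_up2"))),
            ("distal", "down"): (float(self.dofs.get(vec, "psi_rim_d_down")),
                                 float(self.dofs.get(vec, "psi_rim_d_down2")),
                                 float(self.dofs.get(vec, "q_rim_d_down2"))),
        }
        rimvals[("proximal", "down")] = rimvals[("proximal", "up")]

        patches, monolayers = {}, []
        # diaphragm element
        zd0 = self.Zd0.coeffs(self.dofs.get(vec, "zd0"), [0.0, 0.0, z_rim])
        zd2 = self.Zd2.coeffs(self.dofs.get(vec, "zd2"), [0.0, 0.0, z_rim2])
        dmodes = {}
        for pre, side, sgn, key in (("du", "upper", 1.0, ("distal", "up")),
                                    ("dl", "lower", -1.0, ("distal", "down"))):
            r0, r2, rq = rimvals[key]
            p0 = self.Pd0.coeffs(self.dofs.get(vec, f"psi0_{pre}"),
                                 [sgn * math.pi / 2, r0])
            p2 = self.Pd2.coeffs(self.dofs.get(vec, f"psi2_{pre}"), [0.0, r2])
            q2 = self.Qd2.coeffs(self.dofs.get(vec, f"q2_{pre}"), [0.0, rq])
            dmodes[side] = {"psi": {0: p0, 2: p2}, "p": {2: q2}}
        dia = MembranePatch(
            symmetry_class="quarter_turn", order=self.order,
            rho_in_modes={0: 0.0}, rho_out_modes={0: d0, 2: d2},
            z_modes={0: zd0, 2: zd2}, director_modes=dmodes,
            delta0=params.delta0)
        patches["dia"] = dia
        monolayers.append(dict(patch=dia, side="upper", unit="distal_up",
                               label="dia.upper", mult=1, area_mult=1))
        monolayers.append(dict(patch=dia, side="lower", unit="distal_down",
                               label="dia.lower", mult=1, area_mult=1))

        for m in ("up", "down"):
            upper = (m == "up")
            W = float(self.dofs.get(vec, f"W_{m}"))
            rho_s = d0 + W
            if upper:
                z_bg = self._bg_z(z_c)
                bgv = np.asarray(z_bg(rim_of_phi, self._phi))
                w_rim0 = z_rim - _mode_project(bgv, self._phi, np.cos, 0)
                w_rim2 = z_rim2 - _mode_project(bgv, self._phi, np.cos, 2)
                w0_vals = [w_rim0, 0.0, 0.0, 0.0]
                w2_vals = [w_rim2, 0.0, 0.0, 0.0]
            else:
                z_bg = None
                w0_vals = [z_rim, z_ed, 0.0, 0.0]
                w2_vals = [z_rim2, 0.0, 0.0, 0.0]
            w0 = self.W0.coeffs(self.dofs.get(vec, f"w0_{m}"), w0_vals)
            w2 = self.W2.coeffs(self.dofs.get(vec, f"w2_{m}"), w2_vals)
            dmodes = {}
            for leaf, sign in (("proximal", +1), ("distal", -1)):
                tag = "p" if leaf == "proximal" else "d"
                r0, r2, rq = rimvals[(leaf, m)]
                bg = self._bg_angle_modes(rho_s, sign, upper)
                p0 = self.P0.coeffs(self.dofs.get(vec, f"psi0_{tag}_{m}"),
                                    [r0, bg["psi0"], W * bg["dpsi0"]])
                p2 = self.P2.coeffs(self.dofs.get(vec, f"psi2_{tag}_{m}"),
                                    [r2, bg["psi2"]])
                q2 = self.Q2.coeffs(self.dofs.get(vec, f"q2_{tag}_{m}"),
                                    [rq, bg["q2"]])
                dmodes[leaf] = {"psi": {0: p0, 2: p2}, "p": {2: q2}}
            patch = MembranePatch(
                symmetry_class="quarter_turn", order=self.order,
                rho_in_modes={0: d0, 2: d2}, rho_out_modes={0: rho_s},
                z_modes={0: w0, 2: w2}, director_modes=dmodes,
                z_background=z_bg, delta0=params.delta0)
            patches[m] = patch
            dist_unit = "distal_up" if upper else "distal_down"
            monolayers.append(dict(patch=patch, side="proximal", unit="proximal",
                                   label=f"{m}.proximal", mult=1, area_mult=1))
            monolayers.append(dict(patch=patch, side="distal", unit=dist_unit,
                                   label=f"{m}.distal", mult=1, area_mult=1))

        far = [CylinderFarField(
            R=R, L=self.L, rho_fp=d0 + float(self.dofs.get(vec, "W_up")),
            z_c=z_c, leaflets=[(+1, "proximal", 1, 1),
                               (-1, "distal_up", 1, 1)])]
        units = {"proximal": {"A0": None, "reservoir": True},
                 "distal_up": {"A0": None, "reservoir": True},
                 "distal_down": {"A0": None, "reservoir": True}}
        scalars = {"rho_D": d0, "a_x": d0 + d2, "a_y": d0 - d2,
                   "rho_size_up": d0 + float(self.dofs.get(vec, "W_up")),
                   "rho_size_down": d0 + float(self.dofs.get(vec, "W_down")),
                   "h": -z_ed + (z_c - R), "z_c": z_c,
                   "phi_up": float("nan"), "phi_down": float("nan")}
        junctions = [{"a": ("dia.upper", 1), "b": ("up.distal", 0)},
                     {"a": ("dia.lower", 1), "b": ("down.distal", 0)},
                     {"a": ("up.proximal", 0), "b": ("down.proximal", 0)}]
        state = FusionSiteState(
            patches=patches, monolayers=monolayers, units=units, far=far,
            scalars=scalars, compartments=(self.up, self.down),
            symmetry_class="quarter_turn", nx=self.nx, nphi=NPHI,
            problem=self, dof_vector=vec.copy(), junctions=junctions)
        state.junction_mu = getattr(self, "junction_mu", 100.0)
        lipid_accounting(state, self.regime)
        return state

    energy = QuarterTurnStalkProblem.energy
    bounds = QuarterTurnStalkProblem.bounds

    def initial_vector(self, initial: FusionSiteState | None = None) -> np.ndarray:
        """Start from an axisymmetric flat-flat diaphragm solution (the
        cylinder enters through the background), else a generic inflated
        stalk heuristic."""
        vec = np.zeros(self.dofs.n)
        src = initial if (initial is not None and "dia" in initial.patches
                          and initial.symmetry_class == "axisymmetric") else None
        if src is not None:
            d0 = min(8.0, max(0.8, float(src.scalars["rho_D"])))
            W = min(8.0, max(3.5, float(src.scalars["rho_size_up"])
                             - float(src.scalars["rho_D"])))
            z_e = float(poly_eval(src.patches["up"].z_modes[0], 1.0))
            prd = float(poly_eval(
                src.patches["dia"].director_modes["upper"]["psi"][0], 1.0))
            prp = float(src.scalars.get("_psi_rim_p", 0.0))
        else:
            d0, W, z_e, prd, prp = 2.0, 7.0, 3.0, math.pi / 2 + 0.4, 0.0
        prd = min(2.6, max(0.5, prd))
        self.dofs.set(vec, "rho_D", d0)
        self.dofs.set(vec, "z_edge_down", -max(0.5, z_e))
        self.dofs.set(vec, "z_c_off", min(10.0, max(0.0, z_e)))
        self.dofs.set(vec, "psi_rim_p", prp)
        self.dofs.set(vec, "psi_rim_d_up", prd)
        self.dofs.set(vec, "psi_rim_d_down", -prd)
        z_c = self.up.R_c + min(10.0, max(0.0, z_e))
        xg, _ = gauss_nodes(48)
        rim_of_phi = d0 + np.zeros_like(self._phi)

        # diaphragm leaflet angle profiles
        for pre, sgn in (("du", 1.0), ("dl", -1.0)):
            if src is not None:
                pc = src.patches["dia"].director_modes["upper"]["psi"][0]
                prof = sgn * poly_eval(pc, xg)
            else:
                prof = sgn * (math.pi / 2 + (prd - math.pi / 2) * xg)
            self.dofs.set(vec, f"psi0_{pre}", _fit(
                self.Pd0, xg, prof, [sgn * math.pi / 2, sgn * prd]))

        for m in ("up", "down"):
            upper = (m == "up")
            sgn = 1.0 if upper else -1.0
            self.dofs.set(vec, f"W_{m}", W)
            rho_s = d0 + W
            if src is not None:
                sp = src.patches["up"]
                d0s = float(sp.rho_in_modes[0])
                Ws = float(sp.rho_out_modes[0]) - d0s
                xs = np.minimum(1.0, np.maximum(0.0, (d0 + W * xg - d0s)
                                                / max(1e-9, Ws)))
                zprof = sgn * poly_eval(sp.z_modes[0], xs)
            else:
                xs = xg
                zprof = sgn * math.tan(0.7) * 2.5 * (
                    1.0 - np.exp(-(W * xg) / 2.5))
            if upper:
                zbg0 = np.array([_mode_project(np.asarray(
                    self._bg_z(z_c)(d0 + W * x, self._phi)),
                    self._phi, np.cos, 0) for x in xg])
                prof0 = (zprof - zbg0) * (1.0 - xg ** 2) ** 2
                bgr = np.asarray(self._bg_z(z_c)(rim_of_phi, self._phi))
                w0_vals = [0.0 - _mode_project(bgr, self._phi, np.cos, 0),
                           0.0, 0.0, 0.0]
                prof2 = np.array([-_mode_project(np.asarray(
                    self._bg_z(z_c)(d0 + W * x, self._phi)),
                    self._phi, np.cos, 2) for x in xg]) * (1.0 - xg) ** 3
                w2_vals = [0.0 - _mode_project(bgr, self._phi, np.cos, 2),
                           0.0, 0.0, 0.0]
                self.dofs.set(vec, f"w2_{m}", _fit(self.W2, xg, prof2, w2_vals))
            else:
                prof0 = zprof
                w0_vals = [0.0, -max(0.5, z_e), 0.0, 0.0]
            self.dofs.set(vec, f"w0_{m}", _fit(self.W0, xg, prof0, w0_vals))
            for leaf, sign in (("proximal", +1), ("distal", -1)):
                tag = "p" if leaf == "proximal" else "d"
                if src is not None:
                    pc = src.patches["up"].director_modes[leaf]["psi"][0]
                    prof = sgn * poly_eval(pc, xs)
                else:
                    end = sgn * (-math.pi / 2 if leaf == "proximal"
                                 else math.pi / 2)
                    start = prp if leaf == "proximal" else sgn * prd
                    prof = start + (end - start) * xg
                bg = self._bg_angle_modes(rho_s, sign, upper)
                r0 = prp if leaf == "proximal" else sgn * prd
                self.dofs.set(vec, f"psi0_{tag}_{m}", _fit(
                    self.P0, xg, prof, [r0, bg["psi0"], W * bg["dpsi0"]]))
                if upper:
                    prof2 = np.array([self._bg_angle_modes(
                        d0 + W * x, sign, True)["psi2"] for x in xg])
                    profq = np.array([self._bg_angle_modes(
                        d0 + W * x, sign, True)["q2"] for x in xg])
                    self.dofs.set(vec, f"psi2_{tag}_{m}", _fit(
                        self.P2, xg, prof2, [0.0, bg["psi2"]]))
                    self.dofs.set(vec, f"q2_{tag}_{m}", _fit(
                        self.Q2, xg, profq, [0.0, bg["q2"]]))
        return vec
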