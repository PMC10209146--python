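"""Constrained fusion-site configurations.

Builds the degree-of-freedom layouts, boundary conditions and lipid
accounting for the hemifusion stalk and hemifusion diaphragm between the
supported compartment pairings (flat-flat, sphere-sphere, sphere-flat,
cylinder-flat).

Element decomposition: the fusion site consists of the diaphragm (when
present) and one near-site element per membrane, spanning from the stalk
centre / diaphragm rim out to the fusion-site size ρ_size.  ρ_size is
*defined* as the radius where tilt vanishes and the bending matches the
surrounding compartment, so beyond it the membrane is the exact analytic
compartment surface (sphere / cylinder / plane); those far fields enter
the energy in closed form (sphere, plane) or by analytic quadrature
(cylinder footprint) with ρ_size itself a free DOF.

Boundary conditions:

* Stalk centre: the two mid-planes meet on the axis with a fixed 90°
  angle between them (hydrophobic-void avoidance); the merged proximal
  leaflets share a common director there (horizontal for up-down
  symmetric pairings), which makes their dividing surfaces tile the
  hourglass neck continuously; the distal directors are axial so the
  distal dividing surfaces cap the axis smoothly.
* Diaphragm rim (three-way junction): mid-plane positions coincide; the
  rim angles φ_up, φ_down are free; directors are continuous across the
  junction — the proximal leaflets of both membranes share one rim
  director and each membrane's distal leaflet shares its rim director
  with the corresponding diaphragm leaflet.
* Fusion-site edge: mid-plane height free, slope and curvature clamped
  to the compartment's; directors equal the surface normal, so the tilt
  vanishes there exactly.

Lipid accounting: the merged proximal leaflets form one accounting unit;
each distal leaflet (continuing into its diaphragm leaflet) is a separate
unit.  Units touching a flat membrane or an explicit tension reservoir
carry no stretching energy; closed spherical compartments conserve their
enclosed mid-plane volume by adjusting the far-field radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .basis import ConstrainedPoly, cheb_vander, gauss_nodes, poly_eval
from .elastic import MaterialParams, total_energy
from .geometry import GeometryError, MembranePatch, monolayer_grids

__all__ = [
    "CompartmentSpec", "FusionSiteState", "ConfigurationError",
    "build_stalk_configuration", "build_diaphragm_configuration",
    "lipid_accounting", "REGIMES",
]

REGIMES = ("reservoir", "before_flipflop", "after_flipflop")


class ConfigurationError(ValueError):
    """Unsupported pairing or inconsistent constraint regime."""


@dataclass
class CompartmentSpec:
    """Prefusion geometry of one fusing compartment."""

    kind: str                       # "flat" | "sphere" | "cylinder"
    R_c: float | None = None        # mid-plane curvature radius (nm)
    L: float | None = None          # cylinder length (nm)
    fixed_volume: bool = False
    tension_reservoir: bool = False

    def __post_init__(self):
        if self.kind not in ("flat", "sphere", "cylinder"):
            raise ConfigurationError(f"unknown compartment kind {self.kind!r}")
        if self.kind == "flat":
            self.tension_reservoir = True  # infinite membrane = reservoir
            self.fixed_volume = False
        else:
            if self.R_c is None or self.R_c <= 0:
                raise ConfigurationError(f"{self.kind} compartment needs R_c > 0")
        if self.kind == "cylinder":
            if self.L is None or self.L <= 0:
                raise ConfigurationError("cylinder compartment needs L > 0")
            # a long tube is laterally connected to a large reservoir
            self.tension_reservoir = True

    @property
    def curvature(self) -> float:
        """Mid-plane total curvature of the undisturbed compartment."""
        if self.kind == "flat":
            return 0.0
        return (2.0 if self.kind == "sphere" else 1.0) / self.R_c

    def prefusion_volume(self) -> float | None:
        if self.kind == "sphere":
            return 4.0 * np.pi * self.R_c ** 3 / 3.0
        if self.kind == "cylinder":
            return np.pi * self.R_c ** 2 * self.L
        return None

    def leaflet_area(self, sign: int, delta0: float) -> float | None:
        """Prefusion relaxed dividing-plane area of one leaflet (None = ∞)."""
        if self.kind == "flat":
            return None
        Rd = self.R_c + sign * delta0
        if self.kind == "sphere":
            return 4.0 * np.pi * Rd ** 2
        return 2.0 * np.pi * Rd * self.L


# ---------------------------------------------------------------------------
# far-field records
# ---------------------------------------------------------------------------

@dataclass
class SphereFarField:
    """Spherical compartment outside the fusion site (closed forms)."""

    R: float
    theta_e: float                       # attach angle from the fusion pole
    leaflets: list                       # entries (sign, unit, e_mult, a_mult)

    def contributions(self, params: MaterialParams):
        out = []
        cap = 1.0 + np.cos(self.theta_e)
        for sgn, unit, em, am in self.leaflets:
            Rd = self.R + sgn * params.delta0
            J = sgn * 2.0 / Rd
            K = 1.0 / Rd ** 2
            A = 2.0 * np.pi * Rd ** 2 * cap
            parts = {
                "splay": em * A * (0.5 * params.kappa_m * J ** 2
                                   - params.kappa_m * J * params.J_sm),
                "saddle_splay": em * A * params.kappa_bar * K,
                "tilt": 0.0,
            }
            out.append((unit, parts, am * A))
        return out

    def monolayer_density(self, sign: int, params: MaterialParams) -> float:
        Rd = self.R + sign * params.delta0
        J = sign * 2.0 / Rd
        return float(0.5 * params.kappa_m * J ** 2
                     - params.kappa_m * J * params.J_sm
                     + params.kappa_bar / Rd ** 2)


@dataclass
class CylinderFarField:
    """Cylindrical compartment minus the chart footprint of the site."""

    R: float
    L: float
    rho_fp: float                        # chart radius of the near-site footprint
    z_c: float
    leaflets: list                       # entries (sign, unit, e_mult, a_mult)
    nx: int = 24
    nphi: int = 16

    def _footprint_patch(self, params):
        return cylinder_patch(self.R, self.z_c, self.rho_fp, params.delta0)

    def contributions(self, params: MaterialParams):
        patch = self._footprint_patch(params)
        out = []
        for sgn, unit, em, am in self.leaflets:
            Rd = self.R + sgn * params.delta0
            J = sgn / Rd
            A_full = 2.0 * np.pi * Rd * self.L
            u_splay = 0.5 * params.kappa_m * J ** 2 - params.kappa_m * J * params.J_sm
            g = monolayer_grids(patch, "outer" if sgn > 0 else "inner",
                                nx=self.nx, nphi=self.nphi)
            fp_splay = float(((0.5 * params.kappa_m * g["J"] ** 2
                               - params.kappa_m * g["J"] * params.J_sm) * g["dA"]).sum())
            fp_saddle = float((params.kappa_bar * g["K"] * g["dA"]).sum())
            parts = {
                "splay": em * (u_splay * A_full - fp_splay),
                "saddle_splay": em * (0.0 - fp_saddle),
                "tilt": 0.0,
            }
            out.append((unit, parts, am * (A_full - g["area"])))
        return out

    def monolayer_density(self, sign: int, params: MaterialParams) -> float:
        Rd = self.R + sign * params.delta0
        J = sign / Rd
        return float(0.5 * params.kappa_m * J ** 2 - params.kappa_m * J * params.J_sm)


def cylinder_patch(R: float, z_c: float, rho_out: float, delta0: float,
                   lower: bool = True) -> MembranePatch:
    """Analytic patch of a cylinder (axis along x̂ at height z_c) seen as a
    graph over the polar chart of the z = 0 plane; directors are the exact
    surface normals ("outer" points away from the axis)."""
    s = -1.0 if lower else 1.0

    def z_bg(rho, phi):
        y = rho * np.sin(phi)
        return z_c + s * np.sqrt(np.maximum(R ** 2 - y ** 2, 1e-12))

    def normal(rho, phi, sign):
        y = rho * np.sin(phi)
        sb = y / R
        cb = np.sqrt(np.maximum(1.0 - sb ** 2, 0.0))
        # outward normal in chart cyl components (ρ̂, φ̂, ẑ)
        nr = sb * np.sin(phi)
        npp = sb * np.cos(phi)
        nz = s * cb
        return sign * nr, sign * npp, sign * nz

    return MembranePatch(
        symmetry_class="quarter_turn", order=1,
        rho_in_modes={0: 0.0}, rho_out_modes={0: rho_out},
        z_modes={}, director_modes={"outer": {}, "inner": {}},
        z_background=z_bg,
        director_background={"outer": lambda r, p: normal(r, p, +1.0),
                             "inner": lambda r, p: normal(r, p, -1.0)},
        delta0=delta0)


# ---------------------------------------------------------------------------
# fusion-site state
# ---------------------------------------------------------------------------

@dataclass
class FusionSiteState:
    """Assembled fusion-site geometry plus accounting metadata."""

    patches: dict
    monolayers: list
    units: dict
    far: list = field(default_factory=list)
    scalars: dict = field(default_factory=dict)
    compartments: tuple = (None, None)
    symmetry_class: str = "axisymmetric"
    nx: int = 32
    nphi: int | None = None
    problem: object = None
    dof_vector: np.ndarray | None = None
    junctions: list = field(default_factory=list)
    junction_mu: float = 100.0

    def far_contributions(self, params: MaterialParams):
        for rec in self.far:
            yield from rec.contributions(params)

    def translated(self, dz: float) -> "FusionSiteState":
        """Rigidly translated copy along the symmetry axis (z)."""
        import copy
        new = copy.copy(self)
        new.patches = {}
        new.monolayers = []
        for name, p in self.patches.items():
            q = copy.copy(p)
            zm = {k: np.array(v, dtype=float) for k, v in p.z_modes.items()}
            if 0 in zm and len(zm[0]):
                zm[0] = zm[0].copy()
                zm[0][0] += dz
            else:
                zm[0] = np.array([dz])
            q.z_modes = zm
            if p.z_background is not None:
                bg = p.z_background
                q.z_modes = {k: np.array(v, dtype=float) for k, v in p.z_modes.items()}
                q.z_background = (lambda f: (lambda rho, phi: f(rho, phi)))(bg)
                zm2 = dict(q.z_modes)
                base = zm2.get(0, np.zeros(1)).copy()
                if base.size == 0:
                    base = np.zeros(1)
                base = base.copy()
                base[0] += dz
                zm2[0] = base
                q.z_modes = zm2
            new.patches[name] = q
        for rec in self.monolayers:
            r2 = dict(rec)
            for name, q in new.patches.items():
                if self.patches[name] is rec["patch"]:
                    r2["patch"] = q
            new.monolayers.append(r2)
        return new


def lipid_accounting(state: FusionSiteState, regime: str) -> FusionSiteState:
    """Apply a lipid-accounting regime to a built state (in place).

    * ``reservoir``: all units connected to a zero-tension reservoir — no
      stretching energy anywhere.
    * ``before_flipflop``: the merged proximal unit and each distal unit
      keep their prefusion relaxed areas; closed units accumulate
      stretching energy.
    * ``after_flipflop``: flip-flop has relaxed all lateral stretching —
      stretching energy identically zero, volumes unchanged.
    """
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown regime {regime!r}")
    up, down = state.compartments
    if regime == "before_flipflop" and up is not None:
        if up.tension_reservoir and down.tension_reservoir:
            raise ConfigurationError(
                "before_flipflop accounting is incompatible with all-reservoir "
                "compartments; use regime='reservoir'")
    for unit, meta in state.units.items():
        if regime in ("reservoir", "after_flipflop") or meta.get("reservoir", False):
            meta["regime"] = "reservoir" if regime == "reservoir" else regime
            if regime == "before_flipflop":
                meta["regime"] = "reservoir"  # unit-level reservoir override
        else:
            meta["regime"] = regime
    state.scalars["regime"] = regime
    return state


# ---------------------------------------------------------------------------
# axisymmetric problems
# ---------------------------------------------------------------------------

def _sphere_edge(R: float, rho: float, upper: bool):
    """Slope, curvature and outward-normal angle of a sphere's mid-plane at
    chart radius rho.  ``upper`` selects the compartment above the fusion
    site (near-site around its bottom pole)."""
    if rho >= R:
        raise GeometryError("fusion-site size exceeds the compartment radius")
    st = rho / R
    ct = math.sqrt(1.0 - st ** 2)
    if upper:
        slope = rho / (R * ct)
        curv = 1.0 / (R * ct ** 3)
        psi_out = math.atan2(-ct, st)       # outward normal points down-out
    else:
        slope = -rho / (R * ct)
        curv = -1.0 / (R * ct ** 3)
        psi_out = math.atan2(ct, st)        # outward normal points up-out
    return slope, curv, psi_out


def _flat_edge(upper: bool):
    psi_out = -math.pi / 2 if upper else math.pi / 2
    return 0.0, 0.0, psi_out


def edge_conditions(comp: CompartmentSpec, R_eff: float, rho: float, upper: bool):
    """(slope, curvature, ψ_prox, ψ_dist, dψ/dρ) at the fusion-site edge.

    The tilt deformation vanishes at the edge to first order: the director
    equals the surface normal there and rotates with it (dψ/dρ matches the
    normal-angle rate of the compartment surface), so both the tilt and
    the director-gradient splay are continuous with the far field.
    """
    if comp.kind == "flat":
        slope, curv, psi_out = _flat_edge(upper)
        dpsi = 0.0
    elif comp.kind == "sphere":
        slope, curv, psi_out = _sphere_edge(R_eff, rho, upper)
        ct = math.sqrt(1.0 - (rho / R_eff) ** 2)
        dpsi = (1.0 if upper else -1.0) / (R_eff * ct)
    else:
        raise ConfigurationError("axisymmetric edge undefined for cylinders")
    # proximal = outer leaflet (faces the apposed membrane), distal = inner
    psi_prox = psi_out
    psi_dist = psi_out + math.pi if psi_out < 0 else psi_out - math.pi
    return slope, curv, psi_prox, psi_dist, dpsi


class _DofMap:
    """Flat DOF vector <-> named blocks."""

    def __init__(self):
        self.blocks = []   # (name, size, lo, hi, scale)
        self.n = 0

    def add(self, name, size, lo=None, hi=None, scale=1.0):
        self.blocks.append((name, size, lo, hi, self.n, scale))
        self.n += size

    def get(self, vec, name):
        for bname, size, lo, hi, off, scale in self.blocks:
            if bname == name:
                out = vec[off:off + size]
                return out[0] if size == 1 else out
        raise KeyError(name)

    def set(self, vec, name, value):
        for bname, size, lo, hi, off, scale in self.blocks:
            if bname == name:
                vec[off:off + size] = value
                return
        raise KeyError(name)

    def bound(self, name):
        for bname, size, lo, hi, off, scale in self.blocks:
            if bname == name:
                return lo, hi
        raise KeyError(name)

    def bounds(self):
        bl, bu = [], []
        for bname, size, lo, hi, off, scale in self.blocks:
            bl += [lo] * size
            bu += [hi] * size
        return list(zip(bl, bu))

    def pin(self, name, value):
        """Collapse the bounds of one scalar block to a fixed value;
        returns a token for :meth:`unpin`."""
        for i, (bname, size, lo, hi, off, scale) in enumerate(self.blocks):
            if bname == name:
                self.blocks[i] = (bname, size, value, value, off, scale)
                return (i, lo, hi)
        raise KeyError(name)

    def unpin(self, token):
        i, lo, hi = token
        bname, size, _, _, off, scale = self.blocks[i]
        self.blocks[i] = (bname, size, lo, hi, off, scale)


class AxisymStalkProblem:
    """Hemifusion stalk for flat-flat, sphere-sphere and sphere-flat.

    Mirror-symmetric pairings model the upper membrane only and double its
    contributions; the shared proximal director at the stalk centre is then
    horizontal by symmetry and the mid-plane angle parameter α is 45°.
    """

    kind = "stalk"

    def __init__(self, up: CompartmentSpec, down: CompartmentSpec,
                 params: MaterialParams, regime: str = "reservoir",
                 order: int = 8, nx: int = 32):
        pair = (up.kind, down.kind)
        if "cylinder" in pair:
            raise ConfigurationError("cylindrical pairings use the quarter-turn solver")
        if pair not in (("flat", "flat"), ("sphere", "sphere"),
                        ("sphere", "flat"), ("flat", "sphere")):
            raise ConfigurationError(f"unsupported pairing {pair}")
        if pair == ("flat", "sphere"):
            up, down = down, up     # canonical order: curved on top
        for c in (up, down):
            if c.kind != "flat" and c.R_c <= params.delta0:
                raise ConfigurationError("R_c must exceed the tail length delta0")
        self.up, self.down = up, down
        self.params = params
        self.regime = regime
        self.order = order
        self.nx = nx
        self.mirror = (up.kind == down.kind and
                       (up.kind == "flat" or abs(up.R_c - down.R_c) < 1e-12))

        M = order
        # mid-plane: value/slope at centre, value/slope/curvature at edge
        self.Zpoly = ConstrainedPoly(M, [(0.0, 0), (0.0, 1),
                                         (1.0, 0), (1.0, 1), (1.0, 2)])
        # directors: value at centre; value and slope at the edge
        self.Ppoly = ConstrainedPoly(M, [(0.0, 0), (1.0, 0), (1.0, 1)])

        dm = _DofMap()
        membranes = ["up"] if self.mirror else ["up", "down"]
        self.membranes = membranes
        for m in membranes:
            dm.add(f"Z_{m}", self.Zpoly.n_free)
            dm.add(f"psi_p_{m}", self.Ppoly.n_free)
            dm.add(f"psi_d_{m}", self.Ppoly.n_free)
            dm.add(f"rho_size_{m}", 1, 3.0, self._rho_max(m), 1.0)
            dm.add(f"z_edge_{m}", 1, *((0.3, 14.0) if m == "up" else (-14.0, -0.3)))
        if not self.mirror:
            dm.add("alpha", 1, 0.55, 1.02)        # mid-plane angle at the axis
            dm.add("psi_c", 1, -0.7, 0.7)         # shared proximal director
        self.dofs = dm
        self._xg, self._wg = gauss_nodes(nx)
        self._B1 = cheb_vander(self._xg, order, deriv=1)

    def _rho_max(self, m):
        # the fusion site is a local deformation: its size is set by the
        # tilt decay (a few nm); the cap keeps the minimizer from drifting
        # into the slow large-scale bending mode of the far membrane
        comp = self.up if m == "up" else self.down
        if comp.kind == "flat":
            return 12.0
        return min(12.0, 0.6 * comp.R_c)

    # -- geometry assembly --------------------------------------------------

    def _membrane_coeffs(self, vec, m, R_eff):
        comp = self.up if m == "up" else self.down
        upper = (m == "up")
        rho_s = float(self.dofs.get(vec, f"rho_size_{m}"))
        z_e = float(self.dofs.get(vec, f"z_edge_{m}"))
        if self.mirror:
            alpha, psi_c = math.pi / 4, 0.0
        else:
            alpha = float(self.dofs.get(vec, "alpha"))
            psi_c = float(self.dofs.get(vec, "psi_c"))
        slope_c = math.tan(alpha) if upper else math.tan(alpha - math.pi / 2)
        slope_e, curv_e, psi_pe, psi_de, dpsi_e = edge_conditions(
            comp, R_eff, rho_s, upper)
        W = rho_s
        zc = self.Zpoly.coeffs(self.dofs.get(vec, f"Z_{m}"),
                               [0.0, W * slope_c, z_e, W * slope_e, W * W * curv_e])
        psi_dc = math.pi / 2 if upper else -math.pi / 2
        pc = self.Ppoly.coeffs(self.dofs.get(vec, f"psi_p_{m}"),
                               [psi_c, psi_pe, W * dpsi_e])
        dc = self.Ppoly.coeffs(self.dofs.get(vec, f"psi_d_{m}"),
                               [psi_dc, psi_de, W * dpsi_e])
        return rho_s, z_e, zc, pc, dc

    def _near_volume(self, rho_s, zc):
        # π ∫ r² dz along the near-site mid-plane, bottom-up orientation
        r = rho_s * self._xg
        dz = self._B1 @ zc
        return float(np.pi * np.sum(self._wg * r ** 2 * dz))

    def _solve_Reff(self, vec, m):
        comp = self.up if m == "up" else self.down
        if comp.kind != "sphere" or not comp.fixed_volume:
            return comp.R_c if comp.kind != "flat" else None
        V0 = comp.prefusion_volume()
        upper = (m == "up")

        def residual(R):
            rho_s, _, zc, _, _ = self._membrane_coeffs(vec, m, R)
            if rho_s >= R:
                return 1e9
            st = rho_s / R
            ct = math.sqrt(1.0 - st ** 2)
            Vn = self._near_volume(rho_s, zc)
            # spherical zone from the attach circle over the far pole
            Varc = np.pi * R ** 3 * (2.0 / 3.0 + ct - ct ** 3 / 3.0)
            # lower compartment: identical formula with the curve mirrored
            return (Vn if upper else -Vn) + Varc - V0

        lo, hi = 0.85 * comp.R_c, 1.25 * comp.R_c
        flo, fhi = residual(lo), residual(hi)
        if flo * fhi > 0:
            raise GeometryError("volume constraint has no solution in bracket")
        return brentq(residual, lo, hi, xtol=1e-10 * comp.R_c)

    def assemble(self, vec) -> FusionSiteState:
        vec = np.asarray(vec, dtype=float)
        params = self.params
        patches, monolayers, units, far = {}, [], {}, []
        scalars = {"rho_D": 0.0}
        mult = 2 if self.mirror else 1

        unit_names = {"up": ("proximal", "distal_up"),
                      "down": ("proximal", "distal_down")}
        z_edges = {}
        for m in self.membranes:
            comp = self.up if m == "up" else self.down
            R_eff = self._solve_Reff(vec, m)
            rho_s, z_e, zc, pc, dc = self._membrane_coeffs(vec, m, R_eff)
            z_edges[m] = z_e
            patch = MembranePatch(
                symmetry_class="axisymmetric", order=self.order,
                rho_in_modes={0: 0.0}, rho_out_modes={0: rho_s},
                z_modes={0: zc},
                director_modes={"proximal": {"psi": {0: pc}},
                                "distal": {"psi": {0: dc}}},
                delta0=params.delta0)
            patches[m] = patch
            prox_unit, dist_unit = unit_names[m]
            monolayers.append(dict(patch=patch, side="proximal", unit="proximal",
                                   label=f"{m}.proximal", mult=mult, area_mult=mult))
            monolayers.append(dict(patch=patch, side="distal", unit=dist_unit,
                                   label=f"{m}.distal", mult=mult, area_mult=1))
            scalars[f"rho_size_{m}"] = rho_s
            scalars[f"R_eff_{m}"] = R_eff
            if comp.kind == "sphere":
                theta_e = math.asin(rho_s / R_eff)
                far.append(SphereFarField(
                    R=R_eff, theta_e=theta_e,
                    leaflets=[(+1, "proximal", mult, mult),
                              (-1, dist_unit, mult, 1)]))
        if self.mirror:
            scalars["rho_size_down"] = scalars["rho_size_up"]
            scalars["h"] = 2.0 * z_edges["up"]
        else:
            scalars["h"] = z_edges["up"] - z_edges["down"]

        units["proximal"] = {
            "A0": _sum_or_none(self.up.leaflet_area(+1, params.delta0),
                               self.down.leaflet_area(+1, params.delta0)),
            "reservoir": self.up.tension_reservoir or self.down.tension_reservoir,
        }
        units["distal_up"] = {"A0": self.up.leaflet_area(-1, params.delta0),
                              "reservoir": self.up.tension_reservoir,
                              "copies": 2 if self.mirror else 1}
        if self.mirror:
            # mirrored: the (identical) lower distal unit is counted via copies
            pass
        else:
            units["distal_down"] = {"A0": self.down.leaflet_area(-1, params.delta0),
                                    "reservoir": self.down.tension_reservoir}

        if self.mirror:
            junctions = [{"a": ("up.proximal", 0), "b": None}]
        else:
            junctions = [{"a": ("up.proximal", 0), "b": ("down.proximal", 0)}]
        state = FusionSiteState(
            patches=patches, monolayers=monolayers, units=units, far=far,
            scalars=scalars, compartments=(self.up, self.down),
            symmetry_class="axisymmetric", nx=self.nx, nphi=1, problem=self,
            dof_vector=vec.copy(), junctions=junctions)
        state.junction_mu = getattr(self, "junction_mu", 100.0)
        lipid_accounting(state, self.regime)
        return state

    # -- optimisation interface ---------------------------------------------

    def energy(self, vec, params: MaterialParams | None = None) -> float:
        params = params or self.params
        try:
            state = self.assemble(vec)
            bd = total_energy(state, params, nx=self.nx, nphi=1)
        except GeometryError as e:
            # graded penalty: descending it moves trial shapes back into
            # the feasible region
            return 1e6 * (1.0 + e.badness)
        except (ValueError, ZeroDivisionError):
            return 2e7
        if not np.isfinite(bd.total):
            return 2e7
        return bd.total

    def bounds(self):
        return self.dofs.bounds()

    def compose_from_mirror(self, up_state: FusionSiteState,
                            down_state: FusionSiteState) -> np.ndarray:
        """Initial DOFs for a non-mirror pairing composed from two converged
        mirror-symmetric solutions (the lower membrane taken mirrored)."""
        vec = self.initial_vector()
        for m, src_state, flip in (("up", up_state, False),
                                   ("down", down_state, True)):
            patch = src_state.patches["up"]
            rho_s = float(patch.rho_out_modes[0])
            z_e = float(poly_eval(patch.z_modes[0], 1.0))
            comp = self.up if m == "up" else self.down
            upper = (m == "up")
            R_eff = src_state.scalars.get("R_eff_up") or comp.R_c
            self.dofs.set(vec, f"rho_size_{m}", min(rho_s, self._rho_max(m) - 1e-9))
            rho_s = float(self.dofs.get(vec, f"rho_size_{m}"))
            sgn = -1.0 if flip else 1.0
            self.dofs.set(vec, f"z_edge_{m}", sgn * z_e)
            slope_c = math.tan(math.pi / 4) if upper else math.tan(-math.pi / 4)
            slope_e, curv_e, psi_pe, psi_de, dpsi_e = edge_conditions(
                comp, R_eff if comp.kind != "flat" else None, rho_s, upper)
            W = rho_s
            zvals = [0.0, W * slope_c, sgn * z_e, W * slope_e, W * W * curv_e]
            self.dofs.set(vec, f"Z_{m}",
                          self.Zpoly.project(sgn * np.asarray(patch.z_modes[0]), zvals))
            psi_dc = math.pi / 2 if upper else -math.pi / 2
            pc = sgn * np.asarray(patch.director_modes["proximal"]["psi"][0])
            dc = sgn * np.asarray(patch.director_modes["distal"]["psi"][0])
            self.dofs.set(vec, f"psi_p_{m}",
                          self.Ppoly.project(pc, [0.0, psi_pe, W * dpsi_e]))
            self.dofs.set(vec, f"psi_d_{m}",
                          self.Ppoly.project(dc, [psi_dc, psi_de, W * dpsi_e]))
        if not self.mirror:
            self.dofs.set(vec, "alpha", math.pi / 4)
            self.dofs.set(vec, "psi_c", 0.0)
        return vec

    def initial_vector(self) -> np.ndarray:
        vec = np.zeros(self.dofs.n)
        for m in self.membranes:
            upper = (m == "up")
            comp = self.up if m == "up" else self.down
            rho_s = 9.0 if comp.kind == "flat" else min(9.0, 0.45 * comp.R_c)
            sgn = 1.0 if upper else -1.0
            a = 3.0   # boundary-layer height of the 45° core
            R_eff = comp.R_c if comp.kind != "flat" else None

            def sag(rho):
                if comp.kind != "sphere":
                    return 0.0
                return sgn * R_eff * (1.0 - math.sqrt(max(1e-9, 1.0 - (rho / R_eff) ** 2)))

            def ztarget(x):
                rho = rho_s * x
                return sag(rho) + sgn * a * (1.0 - math.exp(-rho / a))

            z_e = ztarget(1.0)
            self.dofs.set(vec, f"rho_size_{m}", rho_s)
            self.dofs.set(vec, f"z_edge_{m}", z_e)
            slope_e, curv_e, psi_pe, psi_de, dpsi_e = edge_conditions(
                comp, R_eff, rho_s, upper)
            W = rho_s
            yz = self.Zpoly.fit(ztarget, [0.0, W * sgn, z_e, W * slope_e, W * W * curv_e])
            self.dofs.set(vec, f"Z_{m}", yz)
            zc = self.Zpoly.coeffs(yz, [0.0, W * sgn, z_e, W * slope_e, W * W * curv_e])

            def slope(x):
                return float(poly_eval(zc, x, deriv=1)) / W

            # directors initially track the mid-plane normals (small tilt),
            # except in the boundary layer near the axis pinned by the BCs
            def normal_down(x):   # angle of the normal pointing below the mid-plane
                return math.atan2(-1.0, slope(x))

            def normal_up(x):
                return math.atan2(1.0, -slope(x))

            prox_n = normal_down if upper else normal_up
            dist_n = normal_up if upper else normal_down
            psi_dc = math.pi / 2 if upper else -math.pi / 2

            def blend(n_fn, v0):
                # smooth hand-off from the axis BC value to normal tracking
                return lambda x: ((1.0 - min(1.0, x / 0.4)) * v0
                                  + min(1.0, x / 0.4) * n_fn(x))
            self.dofs.set(vec, f"psi_p_{m}",
                          self.Ppoly.fit(blend(prox_n, 0.0),
                                         [0.0, psi_pe, W * dpsi_e]))
            self.dofs.set(vec, f"psi_d_{m}",
                          self.Ppoly.fit(blend(dist_n, psi_dc),
                                         [psi_dc, psi_de, W * dpsi_e]))
        if not self.mirror:
            self.dofs.set(vec, "alpha", math.pi / 4)
            self.dofs.set(vec, "psi_c", 0.0)
        return vec


def _sum_or_none(a, b):
    if a is None or b is None:
        return None
    return a + b


class AxisymDiaphragmProblem:
    """Hemifusion diaphragm for flat-flat, sphere-sphere and sphere-flat."""

    kind = "diaphragm"

    def __init__(self, up: CompartmentSpec, down: CompartmentSpec,
                 params: MaterialParams, regime: str = "reservoir",
                 order: int = 8, nx: int = 32):
        pair = (up.kind, down.kind)
        if "cylinder" in pair:
            raise ConfigurationError("cylindrical pairings use the quarter-turn solver")
        if pair not in (("flat", "flat"), ("sphere", "sphere"),
                        ("sphere", "flat"), ("flat", "sphere")):
            raise ConfigurationError(f"unsupported pairing {pair}")
        if pair == ("flat", "sphere"):
            up, down = down, up
        self.up, self.down = up, down
        self.params = params
        self.regime = regime
        self.order = order
        self.nx = nx
        self.mirror = (up.kind == down.kind and
                       (up.kind == "flat" or abs(up.R_c - down.R_c) < 1e-12))

        M = order
        self.Zpoly = ConstrainedPoly(M, [(0.0, 0), (0.0, 1),
                                         (1.0, 0), (1.0, 1), (1.0, 2)])
        self.Ppoly = ConstrainedPoly(M, [(0.0, 0), (1.0, 0), (1.0, 1)])
        # diaphragm mid-plane: symmetric about the axis, rim height free
        self.Zdia = ConstrainedPoly(M, [(0.0, 0), (0.0, 1), (1.0, 0)])
        self.Pdia = ConstrainedPoly(M, [(0.0, 0), (1.0, 0)])

        dm = _DofMap()
        membranes = ["up"] if self.mirror else ["up", "down"]
        self.membranes = membranes
        dm.add("rho_D", 1, 0.25, 9.0)
        # the shared junction director must be its own mirror image for
        # up-down symmetric pairings (horizontal at the rim)
        if self.mirror:
            dm.add("psi_rim_p", 1, 0.0, 0.0)
        else:
            dm.add("psi_rim_p", 1, -1.3, 1.3)
        dm.add("psi_rim_d_up", 1, 0.5, 2.6)
        dm.add("psi_dia_up", self.Pdia.n_free)
        if not self.mirror:
            dm.add("psi_rim_d_down", 1, -2.6, -0.5)
            dm.add("psi_dia_down", self.Pdia.n_free)
            dm.add("Z_dia", self.Zdia.n_free)
            dm.add("z_rim", 1, -6.0, 6.0)
        for m in membranes:
            upper = (m == "up")
            dm.add(f"Z_{m}", self.Zpoly.n_free)
            dm.add(f"psi_p_{m}", self.Ppoly.n_free)
            dm.add(f"psi_d_{m}", self.Ppoly.n_free)
            # annulus width from rim to the tilt-free edge (a few tilt
            # decay lengths; the deformation is local to the junction)
            dm.add(f"W_{m}", 1, 3.5, min(8.0, self._rho_max(m)))
            dm.add(f"z_edge_{m}", 1, *((0.3, 14.0) if upper else (-14.0, -0.3)))
            dm.add(f"phi_{m}", 1, 0.05, 1.25)
        self.dofs = dm
        self._xg, self._wg = gauss_nodes(nx)
        self._B1 = cheb_vander(self._xg, order, deriv=1)

    _rho_max = AxisymStalkProblem._rho_max

    # -- assembly -----------------------------------------------------------

    def _dia_geometry(self, vec):
        rho_D = float(self.dofs.get(vec, "rho_D"))
        if self.mirror:
            zdia = np.zeros(self.order + 1)
            z_rim = 0.0
        else:
            z_rim = float(self.dofs.get(vec, "z_rim"))
            zdia = self.Zdia.coeffs(self.dofs.get(vec, "Z_dia"), [0.0, 0.0, z_rim])
        # mid-plane slope (dz/dρ) of the diaphragm at its rim
        sd = float(poly_eval(zdia, 1.0, deriv=1)) / rho_D
        return rho_D, z_rim, zdia, sd

    def _membrane_coeffs(self, vec, m, R_eff, rho_D, z_rim, sd):
        comp = self.up if m == "up" else self.down
        upper = (m == "up")
        rho_s = rho_D + float(self.dofs.get(vec, f"W_{m}"))
        z_e = float(self.dofs.get(vec, f"z_edge_{m}"))
        phi = float(self.dofs.get(vec, f"phi_{m}"))
        ang = math.atan(sd) + (phi if upper else -phi)
        if abs(ang) > 1.25:
            raise GeometryError("rim angle too steep for the graph chart")
        slope_rim = math.tan(ang)
        slope_e, curv_e, psi_pe, psi_de, dpsi_e = edge_conditions(
            comp, R_eff, rho_s, upper)
        W = rho_s - rho_D
        zc = self.Zpoly.coeffs(self.dofs.get(vec, f"Z_{m}"),
                               [z_rim, W * slope_rim, z_e, W * slope_e, W * W * curv_e])
        psi_rim_p = float(self.dofs.get(vec, "psi_rim_p"))
        psi_rim_d = float(self.dofs.get(vec, f"psi_rim_d_{m}" if not self.mirror
                                        else "psi_rim_d_up"))
        pc = self.Ppoly.coeffs(self.dofs.get(vec, f"psi_p_{m}"),
                               [psi_rim_p, psi_pe, W * dpsi_e])
        dc = self.Ppoly.coeffs(self.dofs.get(vec, f"psi_d_{m}"),
                               [psi_rim_d, psi_de, W * dpsi_e])
        return rho_s, z_e, phi, zc, pc, dc

    def _solve_Reff(self, vec, m, rho_D, z_rim, zdia, sd):
        comp = self.up if m == "up" else self.down
        if comp.kind != "sphere" or not comp.fixed_volume:
            return comp.R_c if comp.kind != "flat" else None
        V0 = comp.prefusion_volume()
        upper = (m == "up")
        sgn = 1.0 if upper else -1.0
        # diaphragm contribution to the enclosed volume (axis to rim)
        r_dia = rho_D * self._xg
        dz_dia = self._B1 @ zdia
        V_dia = float(np.pi * np.sum(self._wg * r_dia ** 2 * dz_dia))

        def residual(R):
            rho_s, _, _, zc, _, _ = self._membrane_coeffs(vec, m, R, rho_D, z_rim, sd)
            if rho_s >= R:
                return 1e9
            ct = math.sqrt(1.0 - (rho_s / R) ** 2)
            r = rho_D + (rho_s - rho_D) * self._xg
            dz = self._B1 @ zc
            Vn = float(np.pi * np.sum(self._wg * r ** 2 * dz))
            Varc = np.pi * R ** 3 * (2.0 / 3.0 + ct - ct ** 3 / 3.0)
            V = sgn * (V_dia + Vn) + Varc
            return V - V0

        lo, hi = 0.85 * comp.R_c, 1.25 * comp.R_c
        if residual(lo) * residual(hi) > 0:
            raise GeometryError("volume constraint has no solution in bracket")
        return brentq(residual, lo, hi, xtol=1e-10 * comp.R_c)

    def assemble(self, vec) -> FusionSiteState:
        vec = np.asarray(vec, dtype=float)
        params = self.params
        patches, monolayers, units, far = {}, [], {}, []
        mult = 2 if self.mirror else 1
        rho_D, z_rim, zdia, sd = self._dia_geometry(vec)

        # diaphragm element
        dia_dirs = {}
        psi_rim_d_up = float(self.dofs.get(vec, "psi_rim_d_up"))
        dia_dirs["upper"] = {"psi": {0: self.Pdia.coeffs(
            self.dofs.get(vec, "psi_dia_up"), [math.pi / 2, psi_rim_d_up])}}
        if not self.mirror:
            psi_rim_d_dn = float(self.dofs.get(vec, "psi_rim_d_down"))
            dia_dirs["lower"] = {"psi": {0: self.Pdia.coeffs(
                self.dofs.get(vec, "psi_dia_down"), [-math.pi / 2, psi_rim_d_dn])}}
        dia = MembranePatch(symmetry_class="axisymmetric", order=self.order,
                            rho_in_modes={0: 0.0}, rho_out_modes={0: rho_D},
                            z_modes={0: zdia}, director_modes=dia_dirs,
                            delta0=params.delta0)
        patches["dia"] = dia
        monolayers.append(dict(patch=dia, side="upper", unit="distal_up",
                               label="dia.upper", mult=mult, area_mult=1))
        if not self.mirror:
            monolayers.append(dict(patch=dia, side="lower", unit="distal_down",
                                   label="dia.lower", mult=1, area_mult=1))

        scalars = {"rho_D": rho_D, "z_rim": z_rim,
                   "_psi_rim_p": float(self.dofs.get(vec, "psi_rim_p"))}
        z_edges = {}
        for m in self.membranes:
            comp = self.up if m == "up" else self.down
            R_eff = self._solve_Reff(vec, m, rho_D, z_rim, zdia, sd)
            rho_s, z_e, phi, zc, pc, dc = self._membrane_coeffs(
                vec, m, R_eff, rho_D, z_rim, sd)
            z_edges[m] = z_e
            patch = MembranePatch(
                symmetry_class="axisymmetric", order=self.order,
                rho_in_modes={0: rho_D}, rho_out_modes={0: rho_s},
                z_modes={0: zc},
                director_modes={"proximal": {"psi": {0: pc}},
                                "distal": {"psi": {0: dc}}},
                delta0=params.delta0)
            patches[m] = patch
            dist_unit = "distal_up" if m == "up" else "distal_down"
            monolayers.append(dict(patch=patch, side="proximal", unit="proximal",
                                   label=f"{m}.proximal", mult=mult, area_mult=mult))
            monolayers.append(dict(patch=patch, side="distal", unit=dist_unit,
                                   label=f"{m}.distal", mult=mult, area_mult=1))
            scalars[f"rho_size_{m}"] = rho_s
            scalars[f"R_eff_{m}"] = R_eff
            scalars[f"phi_{m}"] = phi
            if comp.kind == "sphere":
                theta_e = math.asin(rho_s / R_eff)
                far.append(SphereFarField(
                    R=R_eff, theta_e=theta_e,
                    leaflets=[(+1, "proximal", mult, mult),
                              (-1, dist_unit, mult, 1)]))
        if self.mirror:
            scalars["rho_size_down"] = scalars["rho_size_up"]
            scalars["phi_down"] = scalars["phi_up"]
            scalars["h"] = 2.0 * z_edges["up"]
        else:
            scalars["h"] = z_edges["up"] - z_edges["down"]

        units["proximal"] = {
            "A0": _sum_or_none(self.up.leaflet_area(+1, params.delta0),
                               self.down.leaflet_area(+1, params.delta0)),
            "reservoir": self.up.tension_reservoir or self.down.tension_reservoir,
        }
        units["distal_up"] = {"A0": self.up.leaflet_area(-1, params.delta0),
                              "reservoir": self.up.tension_reservoir,
                              "copies": 2 if self.mirror else 1}
        if not self.mirror:
            units["distal_down"] = {"A0": self.down.leaflet_area(-1, params.delta0),
                                    "reservoir": self.down.tension_reservoir}

        junctions = [{"a": ("dia.upper", 1), "b": ("up.distal", 0)}]
        if self.mirror:
            junctions.append({"a": ("up.proximal", 0), "b": None})
        else:
            junctions.append({"a": ("dia.lower", 1), "b": ("down.distal", 0)})
            junctions.append({"a": ("up.proximal", 0), "b": ("down.proximal", 0)})
        state = FusionSiteState(
            patches=patches, monolayers=monolayers, units=units, far=far,
            scalars=scalars, compartments=(self.up, self.down),
            symmetry_class="axisymmetric", nx=self.nx, nphi=1, problem=self,
            dof_vector=vec.copy(), junctions=junctions)
        state.junction_mu = getattr(self, "junction_mu", 100.0)
        lipid_accounting(state, self.regime)
        return state

    energy = AxisymStalkProblem.energy
    bounds = AxisymStalkProblem.bounds

    def compose_from_mirror(self, up_state: FusionSiteState,
                            down_state: FusionSiteState) -> np.ndarray:
        """Initial DOFs for a non-mirror diaphragm composed from two
        converged mirror-symmetric diaphragm solutions."""
        rho_D = 0.5 * (up_state.scalars["rho_D"] + down_state.scalars["rho_D"])
        vec = self.initial_vector(rho_D0=rho_D)
        self.dofs.set(vec, "rho_D", rho_D)
        self.dofs.set(vec, "z_rim", 0.0)
        self.dofs.set(vec, "Z_dia", np.zeros(self.Zdia.n_free))
        psi_rp = 0.5 * (up_state.scalars.get("_psi_rim_p", 0.0)
                        - down_state.scalars.get("_psi_rim_p", 0.0))
        self.dofs.set(vec, "psi_rim_p", psi_rp)
        for m, src_state, flip in (("up", up_state, False),
                                   ("down", down_state, True)):
            comp = self.up if m == "up" else self.down
            upper = (m == "up")
            sgn = -1.0 if flip else 1.0
            patch = src_state.patches["up"]
            dia_src = src_state.patches["dia"]
            rho_D_src = float(src_state.scalars["rho_D"])
            rho_s = float(patch.rho_out_modes[0]) + rho_D - rho_D_src
            R_eff = src_state.scalars.get("R_eff_up") or comp.R_c
            W = min(8.0, max(3.5, rho_s - rho_D))
            self.dofs.set(vec, f"W_{m}", W)
            rho_s = rho_D + W
            z_e = float(poly_eval(patch.z_modes[0], 1.0))
            self.dofs.set(vec, f"z_edge_{m}", sgn * z_e)
            phi_src = float(src_state.scalars.get("phi_up", 0.6))
            self.dofs.set(vec, f"phi_{m}", phi_src)
            slope_rim = math.tan((1.0 if upper else -1.0) * phi_src)
            slope_e, curv_e, psi_pe, psi_de, dpsi_e = edge_conditions(
                comp, R_eff if comp.kind != "flat" else None, rho_s, upper)
            zvals = [0.0, W * slope_rim, sgn * z_e, W * slope_e, W * W * curv_e]
            zc = sgn * np.asarray(patch.z_modes[0])
            zc = zc - zc[0] + 0.0  # rim pinned at the dia plane
            self.dofs.set(vec, f"Z_{m}", self.Zpoly.project(zc, zvals))
            psi_dc = math.pi / 2 if upper else -math.pi / 2
            prd = sgn * float(poly_eval(
                dia_src.director_modes["upper"]["psi"][0], 1.0))
            key = "psi_rim_d_up" if upper else "psi_rim_d_down"
            lo, hi = [(b[2], b[3]) for b in self.dofs.blocks if b[0] == key][0]
            prd = min(hi, max(lo, prd))
            self.dofs.set(vec, key, prd)
            pc = sgn * np.asarray(patch.director_modes["proximal"]["psi"][0])
            dc = sgn * np.asarray(patch.director_modes["distal"]["psi"][0])
            self.dofs.set(vec, f"psi_p_{m}",
                          self.Ppoly.project(pc, [psi_rp, psi_pe, W * dpsi_e]))
            self.dofs.set(vec, f"psi_d_{m}",
                          self.Ppoly.project(dc, [prd, psi_de, W * dpsi_e]))
            dia_c = sgn * np.asarray(dia_src.director_modes["upper"]["psi"][0])
            self.dofs.set(vec, "psi_dia_up" if upper else "psi_dia_down",
                          self.Pdia.project(sgn * dia_c if False else dia_c,
                                            [psi_dc, prd]))
        return vec

    def initial_vector(self, stalk_state: FusionSiteState | None = None,
                       phi0: float = 0.8, rho_D0: float | None = None,
                       blend_width: float = 0.5) -> np.ndarray:
        """Heuristic start: a stalk inflated to a small rim radius.

        With a converged stalk supplied, its fields are resampled onto the
        annular charts so the initial diaphragm energy continuously extends
        the stalk energy as ρ_D → 0.
        """
        vec = np.zeros(self.dofs.n)
        if rho_D0 is None:
            rho_D0 = 1.8 if stalk_state is not None else 2.0
        self.dofs.set(vec, "rho_D", rho_D0)
        psi_rim_d0 = {}
        for m in self.membranes:
            upper = (m == "up")
            comp = self.up if m == "up" else self.down
            sgn = 1.0 if upper else -1.0
            sp = None
            if stalk_state is not None:
                sname = m if m in stalk_state.patches else "up"
                sp = stalk_state.patches[sname]
                rho_s_old = float(sp.rho_out_modes[0])
                rho_s = rho_s_old
                z_e = float(poly_eval(sp.z_modes[0], 1.0))
                if not upper and sname == "up":
                    z_e = -z_e
            else:
                rho_s = 9.0 if comp.kind == "flat" else min(9.0, 0.45 * comp.R_c)
            a = 3.0
            R_eff = comp.R_c if comp.kind != "flat" else None

            def sag(rho):
                if comp.kind != "sphere":
                    return 0.0
                s = lambda r: R_eff * (1.0 - math.sqrt(max(1e-9, 1.0 - (r / R_eff) ** 2)))
                return sgn * (s(rho) - s(rho_D0))

            W = rho_s - rho_D0

            if sp is not None and sp.symmetry_class == "axisymmetric":
                flip = not (upper or m in stalk_state.patches)
                v_rim = float(poly_eval(sp.z_modes[0], rho_D0 / rho_s))

                def zt(x):
                    rho = rho_D0 + W * x
                    v = float(poly_eval(sp.z_modes[0], min(1.0, rho / rho_s))) - v_rim
                    return -v if flip else v
                sd0 = float(poly_eval(sp.z_modes[0], rho_D0 / rho_s, deriv=1)) / rho_s
                phi0 = min(phi0, max(0.15, math.atan(abs(sd0))))
                z_e = zt(1.0)
            else:
                def zt(x):
                    rho = rho_D0 + W * x
                    return sag(rho) + sgn * math.tan(phi0) * a * (
                        1.0 - math.exp(-(rho - rho_D0) / a))
                z_e = zt(1.0)
            self.dofs.set(vec, f"W_{m}", min(8.0, max(3.5, W)))
            W = float(self.dofs.get(vec, f"W_{m}"))
            rho_s = rho_D0 + W
            self.dofs.set(vec, f"z_edge_{m}", z_e)
            self.dofs.set(vec, f"phi_{m}", phi0)
            slope_e, curv_e, psi_pe, psi_de, dpsi_e = edge_conditions(
                comp, R_eff, rho_s, upper)
            slope_rim = math.tan(sgn * phi0)
            zvals = [0.0, W * slope_rim, z_e, W * slope_e, W * W * curv_e]
            yz = self.Zpoly.fit(zt, zvals)
            self.dofs.set(vec, f"Z_{m}", yz)
            zc = self.Zpoly.coeffs(yz, zvals)

            def slope(x):
                return float(poly_eval(zc, x, deriv=1)) / W

            def normal_down(x):
                return math.atan2(-1.0, slope(x))

            def normal_up(x):
                return math.atan2(1.0, -slope(x))

            prox_n = normal_down if upper else normal_up
            dist_n = normal_up if upper else normal_down
            # junction directors: proximal wraps the outer wedge
            # (horizontal); distal bisects diaphragm and membrane normals
            prd = sgn * (math.pi / 2 + 0.5 * phi0)
            psi_rim_d0[m] = prd

            def blend(n_fn, v0):
                return lambda x: ((1.0 - min(1.0, x / blend_width)) * v0
                                  + min(1.0, x / blend_width) * n_fn(x))
            self.dofs.set(vec, f"psi_p_{m}",
                          self.Ppoly.fit(blend(prox_n, 0.0),
                                         [0.0, psi_pe, W * dpsi_e]))
            self.dofs.set(vec, f"psi_d_{m}",
                          self.Ppoly.fit(blend(dist_n, prd),
                                         [prd, psi_de, W * dpsi_e]))
            if upper:
                self.dofs.set(vec, "psi_rim_p", 0.0)
                self.dofs.set(vec, "psi_rim_d_up", prd)
                if not self.mirror:
                    self.dofs.set(vec, "z_rim", 0.0)
            elif not self.mirror:
                self.dofs.set(vec, "psi_rim_d_down", prd)
        # diaphragm leaflet directors: vertical at the axis, rim value at rim
        prd = psi_rim_d0["up"]
        self.dofs.set(vec, "psi_dia_up",
                      self.Pdia.fit(lambda x: math.pi / 2 + (prd - math.pi / 2) * x,
                                    [math.pi / 2, prd]))
        if not self.mirror:
            prdd = psi_rim_d0["down"]
            self.dofs.set(vec, "psi_dia_down",
                          self.Pdia.fit(lambda x: -math.pi / 2 + (prdd + math.pi / 2) * x,
                                        [-math.pi / 2, prdd]))
        return vec


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def _first_feasible(prob, candidates):
    """Assemble the lowest-energy candidate initial vector; if none is
    feasible, return the least-bad one (graded penalties let the minimizer
    recover)."""
    best, best_E = None, np.inf
    for kw in candidates:
        try:
            vec = prob.initial_vector(**kw)
        except Exception:
            continue
        E = prob.energy(vec)
        if E < best_E:
            best, best_E = vec, E
    if best is None:
        raise ConfigurationError("no valid initial shape found")
    return prob.assemble(best)


def build_stalk_configuration(up: CompartmentSpec, down: CompartmentSpec,
                              params: MaterialParams, regime: str = "reservoir",
                              order: int = 8, nx: int = 32) -> FusionSiteState:
    """Initial hemifusion-stalk state (ρ_D = 0, 90° axis constraint) with its
    attached optimisation problem (``state.problem``)."""
    if up.kind == "cylinder" or down.kind == "cylinder":
        from .quarter_turn import QuarterTurnStalkProblem
        prob = QuarterTurnStalkProblem(up, down, params, regime=regime)
        return prob.assemble(prob.initial_vector())
    prob = AxisymStalkProblem(up, down, params, regime=regime,
                              order=order, nx=nx)
    return _first_feasible(prob, [{}])


def build_diaphragm_configuration(up: CompartmentSpec, down: CompartmentSpec,
                                  params: MaterialParams, regime: str = "reservoir",
                                  initial: FusionSiteState | None = None,
                                  order: int = 8, nx: int = 32) -> FusionSiteState:
    """Initial hemifusion-diaphragm state (free rim radius and rim angles).

    With ``initial`` (a converged stalk state) the start is that stalk
    inflated to a small rim radius, which keeps the local minimization on
    the diaphragm branch continuously connected to the stalk.
    """
    if up.kind == "cylinder" or down.kind == "cylinder":
        from .quarter_turn import QuarterTurnDiaphragmProblem
        prob = QuarterTurnDiaphragmProblem(up, down, params, regime=regime)
        return prob.assemble(prob.initial_vector(initial))
    prob = AxisymDiaphragmProblem(up, down, params, regime=regime,
                                  order=order, nx=nx)
    # candidate groups in order of preference: a moderate rim radius on
    # the equilibrium branch first, other radii only as fallbacks
    groups = []
    for rd0 in (None, 2.6, 1.6, 3.4):
        groups.append([dict(stalk_state=initial, phi0=phi0,
                            blend_width=bw, rho_D0=rd0)
                       for phi0 in (0.8, 0.65, 0.95)
                       for bw in (0.5, 0.7, 0.35)])
    if initial is not None:
        # cold-start fallbacks in case the resampled warm starts are all
        # infeasible for this pairing
        for rd0 in (None, 2.6, 1.6):
            groups.append([dict(stalk_state=None, phi0=phi0,
                                blend_width=bw, rho_D0=rd0)
                           for phi0 in (0.8, 0.65, 0.95)
                           for bw in (0.5, 0.7, 0.35)])
    best_cfg = None
    best_E = np.inf
    for group in groups:
        cfg = _first_feasible(prob, group)
        E = prob.energy(cfg.dof_vector)
        if E < best_E:
            best_cfg, best_E = cfg, E
        if E < 5e4:
            return cfg
    return best_cfg
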