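"""Monolayer elastic energy: density, tension, totals, prefusion references.

The quadratic tilt-splay energy density of a lipid monolayer is

    u = ½ κ_m J̃² − κ_m J̃ J_sm + κ̄_m K̃ + ½ κ_t t² + γ_m

with splay J̃, saddle splay K̃, tilt t, monolayer tension γ_m, bending
rigidity κ_m, saddle-splay modulus κ̄_m = χ κ_m, tilt modulus
κ_t = κ_m/l², and mean lipid intrinsic curvature J_sm.  The reference
state (flat, tilt-free, relaxed) has zero energy.

Stretching enters the total energy once per monolayer accounting unit as
the global quadratic form ½ K_m (A − A0)²/A0 whose derivative reproduces
the tension γ_m = K_m (A − A0)/A0; the γ_m density term is only used when
evaluating local stress maps for pore energetics (integrating a constant
tension over the area as well would double count the stretching energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import monolayer_grids
from .units import parse_quantity

__all__ = [
    "MaterialParams", "LipidComponent", "EnergyBreakdown",
    "mean_intrinsic_curvature", "energy_density", "monolayer_tension",
    "total_energy", "prefusion_energy", "CompositionError",
]


class CompositionError(ValueError):
    """Lipid mole fractions do not sum to one."""


@dataclass
class MaterialParams:
    """Monolayer material constants in the internal nm / k_BT unit system.

    ``K_m`` and ``lambda_rim`` accept dimensioned strings ("80 mN/m",
    "15 pN") which are converted on construction.
    """

    kappa_m: float = 10.0          # bending rigidity, k_BT
    chi: float = -0.5              # saddle-splay ratio κ̄_m/κ_m
    l: float = 1.2                 # tilt decay length, nm
    J_sm: float = -0.22            # mean lipid intrinsic curvature, nm^-1
    delta0: float = 1.5            # undeformed tail length, nm
    K_m: float | str = "80 mN/m"   # stretching modulus
    lambda_rim: float | str = "15 pN"  # pore rim line tension

    def __post_init__(self):
        self.K_m = parse_quantity(self.K_m)
        self.lambda_rim = parse_quantity(self.lambda_rim)
        if self.kappa_m <= 0:
            raise ValueError("kappa_m must be positive")
        if not -1.0 <= self.chi <= 0.0:
            raise ValueError("chi must lie in [-1, 0]")
        if self.l <= 0 or self.delta0 <= 0:
            raise ValueError("l and delta0 must be positive")
        if self.K_m < 0 or self.lambda_rim < 0:
            raise ValueError("K_m and lambda_rim must be non-negative")

    @property
    def kappa_bar(self) -> float:
        return self.chi * self.kappa_m

    @property
    def kappa_t(self) -> float:
        return self.kappa_m / self.l ** 2

    def replace(self, **kw) -> "MaterialParams":
        d = {k: getattr(self, k) for k in
             ("kappa_m", "chi", "l", "J_sm", "delta0", "K_m", "lambda_rim")}
        d.update(kw)
        return MaterialParams(**d)


@dataclass
class LipidComponent:
    zeta: float          # intrinsic curvature, nm^-1
    mole_fraction: float


def mean_intrinsic_curvature(components) -> float:
    """Mole-fraction weighted intrinsic curvature of a lipid mixture."""
    comps = list(components)
    if not comps:
        raise CompositionError("at least one lipid component required")
    total = sum(c.mole_fraction for c in comps)
    if abs(total - 1.0) > 1e-6:
        raise CompositionError(f"mole fractions sum to {total}, not 1")
    return float(sum(c.zeta * c.mole_fraction for c in comps))


def energy_density(J, K, tilt, gamma_m, params: MaterialParams):
    """Tilt-splay energy density (k_BT/nm²) at given deformations."""
    t2 = np.asarray(tilt, dtype=float)
    if t2.ndim and t2.shape[-1] == 3:
        t2 = np.sum(t2 * t2, axis=-1)
    else:
        t2 = t2 ** 2 if t2.ndim == 0 else t2
    return (0.5 * params.kappa_m * np.asarray(J) ** 2
            - params.kappa_m * np.asarray(J) * params.J_sm
            + params.kappa_bar * np.asarray(K)
            + 0.5 * params.kappa_t * t2
            + gamma_m)


def monolayer_tension(area: float, relaxed_area: float, K_m: float):
    """Tension γ_m = K_m (A − A0)/A0 and stretching energy ½K_m(A−A0)²/A0."""
    if area <= 0 or relaxed_area <= 0:
        raise ValueError("areas must be positive")
    strain = (area - relaxed_area) / relaxed_area
    gamma = K_m * strain
    energy = 0.5 * K_m * (area - relaxed_area) ** 2 / relaxed_area
    return gamma, energy


@dataclass
class EnergyBreakdown:
    """Energy decomposition of a fusion-site state (all in k_BT)."""

    splay: dict = field(default_factory=dict)        # monolayer label -> k_BT
    fold_penalty: float = 0.0                        # numerical barrier (k_BT)
    junction_penalty: float = 0.0                    # tilt-continuity enforcement
    junction_tilt_mismatch: float = 0.0              # max |Δt| at junctions
    tilt: dict = field(default_factory=dict)
    saddle_splay: dict = field(default_factory=dict)
    stretching: dict = field(default_factory=dict)   # accounting unit -> k_BT
    tension: dict = field(default_factory=dict)      # accounting unit -> k_BT/nm²
    areas: dict = field(default_factory=dict)        # accounting unit -> nm²
    total: float = 0.0
    reference: float = 0.0   # prefusion reference subtracted by callers

    @property
    def bending_total(self) -> float:
        return (sum(self.splay.values()) + sum(self.tilt.values())
                + sum(self.saddle_splay.values()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = {"energies": "kBT", "tension": "kBT/nm^2", "areas": "nm^2"}
        return d


def junction_tilt_penalty(state, grids, mu: float = 100.0):
    """Stiff penalty enforcing equal lipid tilt on both sides of each
    three-way junction (monolayer dividing surfaces tangent-continuous
    across the rim).  Returns (penalty energy, max |Δt| over junctions).

    ``state.junctions`` lists dicts with keys a=(patch_label, end),
    b=(patch_label, end) or b=None for mirror-symmetric junctions (where
    the condition is that the tilt has no axial component).
    """
    pen = 0.0
    worst = 0.0
    for j in getattr(state, "junctions", []):
        la, ea = j["a"]
        ga = grids[la][f"edge{ea}"]
        r = np.atleast_1d(ga["r"])
        if j.get("b") is None:
            dt = 2.0 * np.atleast_2d(ga["t"])[2:3, :]   # mirror: t_z -> -t_z
        else:
            lb, eb = j["b"]
            gb = grids[lb][f"edge{eb}"]
            sb = j.get("flip_b", 1.0)
            dt = np.atleast_2d(ga["t"]) - sb * np.atleast_2d(gb["t"])
        d2 = np.sum(np.asarray(dt) ** 2, axis=0)
        worst = max(worst, float(np.sqrt(d2.max())))
        # ∮ |Δt|² dl over the junction ring
        circ = 2.0 * np.pi * np.maximum(r, 1e-6)
        pen += mu * float(np.mean(d2 * circ))
    return pen, worst


def total_energy(state, params: MaterialParams, nx: int | None = None,
                 nphi: int | None = None, strict: bool = False) -> EnergyBreakdown:
    """Integrate the monolayer energy density over every dividing plane of a
    fusion-site state, plus global stretching terms per accounting unit.

    ``state`` duck-types :class:`~hemifusion.configurations.FusionSiteState`:
    it provides ``monolayers`` records (patch, side, unit, label, mult),
    ``far_contributions(params)`` and ``units`` accounting metadata.
    """
    bd = EnergyBreakdown()
    areas = {}
    grids = {}
    nx = nx or getattr(state, "nx", 32)
    nphi = nphi if nphi is not None else getattr(state, "nphi", None)
    for rec in state.monolayers:
        g = monolayer_grids(rec["patch"], rec["side"], nx=nx, nphi=nphi,
                            strict=strict)
        m = rec.get("mult", 1)
        lab = rec["label"]
        grids[lab] = g
        ksp = 0.5 * params.kappa_m * g["J"] ** 2 - params.kappa_m * g["J"] * params.J_sm
        bd.splay[lab] = bd.splay.get(lab, 0.0) + m * float((ksp * g["dA"]).sum())
        bd.tilt[lab] = bd.tilt.get(lab, 0.0) + m * float(
            (0.5 * params.kappa_t * g["t2"] * g["dA"]).sum())
        bd.saddle_splay[lab] = bd.saddle_splay.get(lab, 0.0) + m * float(
            (params.kappa_bar * g["K"] * g["dA"]).sum())
        am = rec.get("area_mult", m)
        areas[rec["unit"]] = areas.get(rec["unit"], 0.0) + am * g["area"]
        bd.fold_penalty += m * g.get("fold_penalty", 0.0)
    for unit, parts, area in state.far_contributions(params):
        for key, val in parts.items():
            getattr(bd, key)[f"far.{unit}"] = getattr(bd, key).get(f"far.{unit}", 0.0) + val
        areas[unit] = areas.get(unit, 0.0) + area
    bd.areas = areas
    for unit, meta in state.units.items():
        regime = meta.get("regime", "reservoir")
        copies = meta.get("copies", 1)
        if regime == "before_flipflop" and meta.get("A0"):
            gamma, Us = monolayer_tension(areas[unit], meta["A0"], params.K_m)
            bd.tension[unit] = gamma
            bd.stretching[unit] = copies * Us
        else:
            bd.tension[unit] = 0.0
            bd.stretching[unit] = 0.0
    jp, jworst = junction_tilt_penalty(state, grids,
                                       mu=getattr(state, "junction_mu", 100.0))
    bd.junction_penalty = jp
    bd.junction_tilt_mismatch = jworst
    bd.total = (bd.bending_total + sum(bd.stretching.values())
                + bd.fold_penalty + bd.junction_penalty)
    return bd


def prefusion_energy(compartment, params: MaterialParams) -> float:
    """Closed-form prefusion elastic energy of a compartment (k_BT).

    Flat compartments have zero energy; spheres cost
    16πκ_m(1 − δ0 J_sm) + 8πκ̄_m independent of radius; cylinders of length
    L cost 2πκ_m R L/(R² − δ0²).
    """
    kind = getattr(compartment, "kind", compartment)
    if kind == "flat":
        return 0.0
    if kind == "sphere":
        return float(16.0 * np.pi * params.kappa_m * (1.0 - params.delta0 * params.J_sm)
                     + 8.0 * np.pi * params.kappa_bar)
    if kind == "cylinder":
        R, L = compartment.R_c, compartment.L
        if R <= params.delta0:
            raise ValueError("cylinder radius must exceed the tail length")
        if L is None or L <= 0:
            raise ValueError("cylinder length must be positive")
        return float(2.0 * np.pi * params.kappa_m * R * L / (R ** 2 - params.delta0 ** 2))
    raise ValueError(f"unknown compartment kind {kind!r}")
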