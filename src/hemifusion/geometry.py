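"""Membrane elements and monolayer differential geometry.

A membrane element is a mid-plane surface plus one lipid-director field per
leaflet.  Surfaces are charts over polar coordinates (ρ, φ): the mid-plane
height z and the director components are low-order Fourier series in φ
(constant for axisymmetric elements, cos 2kφ / sin 2kφ modes for
quarter-turn ones) whose radial profiles are polynomials in the scaled
coordinate x = (ρ − ρ_in)/(ρ_out − ρ_in).

All vector grids carry components in the local cylindrical frame
(ρ̂(φ), φ̂(φ), ẑ); azimuthal derivatives therefore pick up the frame terms
∂φ ρ̂ = φ̂ and ∂φ φ̂ = −ρ̂.

For each monolayer the dividing plane sits at R± = R_mp + δ n̂± with the
tail length δ = δ0 √(1 + t²) and the tilt t measured against the
dividing-plane normal.  The implicit relation is resolved by one explicit
correction step (tilt evaluated on the δ0-offset surface), with the
lengthening smoothed and saturated at 1.6 δ0 — see monolayer_grids for the
rationale.  Splay J̃ and saddle
splay K̃ are the trace and determinant of the director-gradient tensor on
the dividing plane; in the tilt-free limit they reduce to c1 + c2 and
c1 · c2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import (endpoint_weights, fourier_diff_matrix, gauss_diff_matrix,
                    gauss_nodes, poly_eval, smoothing_projector)

__all__ = [
    "MembranePatch",
    "SurfaceFrame",
    "TiltState",
    "GeometryError",
    "DegenerateDirectorError",
    "tilt_vector",
    "tail_length",
    "splay_and_saddle",
    "offset_dividing_plane",
    "monolayer_grids",
]


class GeometryError(ValueError):
    """Invalid membrane geometry (self-intersection, folded chart, ...).

    ``badness`` grades how far the geometry is from feasibility so that
    optimizers can use it as a descent direction out of infeasible trials.
    """

    def __init__(self, msg, badness: float = 1.0):
        super().__init__(msg)
        self.badness = float(badness)


class DegenerateDirectorError(GeometryError):
    """Lipid director (anti)parallel to the surface plane."""


# ---------------------------------------------------------------------------
# pointwise operations
# ---------------------------------------------------------------------------

def tilt_vector(director: np.ndarray, normal: np.ndarray,
                tol: float = 1e-8) -> np.ndarray:
    """Lipid tilt t = n/(n·N) − N.

    The result lies in the tangent plane of the surface whose unit normal
    is N; |t| = tan θ for a director at angle θ to the normal.
    """
    n = np.asarray(director, dtype=float)
    N = np.asarray(normal, dtype=float)
    c = float(np.dot(n, N))
    if c <= tol:
        raise DegenerateDirectorError(
            f"director·normal = {c:.3g} <= {tol}: lipid lies in the surface plane")
    return n / c - N


def tail_length(tilt: np.ndarray, delta0: float) -> float:
    """Tail length δ = δ0 √(1 + |t|²) (= δ0/cos θ for tilt angle θ)."""
    if delta0 <= 0:
        raise ValueError("delta0 must be positive")
    t = np.asarray(tilt, dtype=float)
    return float(delta0 * np.sqrt(1.0 + np.dot(t, t)))


# ---------------------------------------------------------------------------
# membrane patches
# ---------------------------------------------------------------------------

@dataclass
class MembranePatch:
    """One membrane element: mid-plane chart + per-leaflet directors.

    Scalar fields are stored as ``{mode: coeff_array}`` dictionaries where
    ``mode`` is the azimuthal wavenumber (0, 2, 4).  Mid-plane height and
    the (ρ, z) director components use cosine modes; the φ̂ director
    component uses sine modes (odd under the quarter-turn reflections).

    ``z_background`` / ``director_background`` optionally hold analytic
    callables (ρ, φ) → value describing the undeformed compartment surface
    on which the polynomial fields ride (used for curved compartments so
    the polynomials only represent the deformation).
    """

    symmetry_class: str                       # "axisymmetric" | "quarter_turn"
    order: int
    rho_in_modes: dict = field(default_factory=lambda: {0: 0.0})
    rho_out_modes: dict = field(default_factory=lambda: {0: 10.0})
    z_modes: dict = field(default_factory=dict)
    director_modes: dict = field(default_factory=dict)  # side -> comp -> {mode: coeffs}
    z_background: object = None
    director_background: dict = field(default_factory=dict)  # side -> callable(rho, phi) -> (3, ...)
    delta0: float = 1.5

    def radial_extent(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rin = sum(v * np.cos(k * phi) for k, v in self.rho_in_modes.items())
        rout = sum(v * np.cos(k * phi) for k, v in self.rho_out_modes.items())
        return np.broadcast_to(rin, phi.shape).copy(), np.broadcast_to(rout, phi.shape).copy()

    # -- field evaluation ---------------------------------------------------
    def _eval_modes(self, modes: dict, x, phi, trig=np.cos):
        out = 0.0
        for k, coeffs in modes.items():
            out = out + poly_eval(coeffs, x) * trig(k * phi)
        return np.broadcast_to(out, np.broadcast(x, phi).shape).copy()

    def midplane_z(self, x, phi):
        phi = np.asarray(phi, dtype=float)
        x = np.asarray(x, dtype=float)
        z = self._eval_modes(self.z_modes, x, phi)
        if self.z_background is not None:
            rho = self.rho_of(x, phi)
            z = z + self.z_background(rho, phi)
        return z

    def rho_of(self, x, phi):
        phi = np.asarray(phi, dtype=float)
        rin = sum(v * np.cos(k * phi) for k, v in self.rho_in_modes.items())
        rout = sum(v * np.cos(k * phi) for k, v in self.rho_out_modes.items())
        return rin + np.asarray(x, dtype=float) * (rout - rin)

    def director_components(self, side: str, x, phi):
        """Unnormalized director components (ρ̂, φ̂, ẑ) at chart points.

        Two representations: explicit components ("r", "p", "z" mode sets)
        riding on an optional analytic background, or an in-plane angle
        field ("psi", measured from ρ̂ towards ẑ) plus an optional "p"
        azimuthal component — the latter guarantees near-unit directors and
        is used for axisymmetric elements.
        """
        comp_modes = self.director_modes[side]
        shape = np.broadcast(np.asarray(x, float), np.asarray(phi, float)).shape
        if "psi" in comp_modes:
            psi = self._eval_modes(comp_modes["psi"], x, phi)
            npp = self._eval_modes(comp_modes.get("p", {}), x, phi, trig=np.sin)
            return (np.broadcast_to(np.cos(psi), shape).copy(),
                    np.broadcast_to(npp, shape).copy(),
                    np.broadcast_to(np.sin(psi), shape).copy())
        nr = self._eval_modes(comp_modes.get("r", {}), x, phi)
        npp = self._eval_modes(comp_modes.get("p", {}), x, phi, trig=np.sin)
        nz = self._eval_modes(comp_modes.get("z", {}), x, phi)
        if side in self.director_background and self.director_background[side] is not None:
            rho = self.rho_of(x, phi)
            br, bp, bz = self.director_background[side](rho, phi)
            nr, npp, nz = nr + br, npp + bp, nz + bz
        return (np.broadcast_to(nr, shape).copy(),
                np.broadcast_to(npp, shape).copy(),
                np.broadcast_to(nz, shape).copy())


@dataclass
class SurfaceFrame:
    """Evaluated frame on a dividing plane at one quadrature point."""
    position: np.ndarray
    tangents: tuple
    normal: np.ndarray
    dA: float
    c1: float = np.nan
    c2: float = np.nan


@dataclass
class TiltState:
    tilt: np.ndarray
    delta: float


# ---------------------------------------------------------------------------
# grid machinery
# ---------------------------------------------------------------------------

def _dphi_vec(Fr, Fp, Fz, Dphi):
    """Azimuthal derivative of a vector grid in the rotating cyl frame."""
    return (Fr @ Dphi.T - Fp, Fp @ Dphi.T + Fr, Fz @ Dphi.T)


def monolayer_grids(patch: MembranePatch, side: str, nx: int = 32,
                    nphi: int | None = None, full_output: bool = False,
                    strict: bool = True) -> dict:
    """Evaluate all monolayer quantities of one leaflet on a quadrature grid.

    Returns a dict with grids (nx, nphi): ``J`` (splay, nm^-1), ``K``
    (saddle splay, nm^-2), ``t2`` (squared tilt), ``dA`` (area weights,
    already multiplied by the quadrature weights so ``dA.sum()`` is the
    dividing-plane area), plus positions and directors when
    ``full_output``.
    """
    if nphi is None:
        nphi = 1 if patch.symmetry_class == "axisymmetric" else 16
    xg, wx = gauss_nodes(nx)
    Dx = gauss_diff_matrix(nx)
    if nphi == 1:
        phig = np.array([0.0])
        wphi = np.array([2.0 * np.pi])
        Dphi = np.zeros((1, 1))
    else:
        phig = np.arange(nphi) * 2.0 * np.pi / nphi
        wphi = np.full(nphi, 2.0 * np.pi / nphi)
        Dphi = fourier_diff_matrix(nphi)

    X, PHI = np.meshgrid(xg, phig, indexing="ij")

    # mid-plane position grids (cyl components)
    Pr = patch.rho_of(X, PHI)
    Pp = np.zeros_like(Pr)
    Pz = patch.midplane_z(X, PHI)

    e1m = (Dx @ Pr, np.zeros_like(Pr), Dx @ Pz)
    e2m = _dphi_vec(Pr, Pp, Pz, Dphi)
    Nm = _cross(e1m, e2m)
    Nm = _normalize(Nm)

    nr, npp, nz = patch.director_components(side, X, PHI)
    nn = np.sqrt(nr * nr + npp * npp + nz * nz)
    if np.any(nn < 1e-12):
        raise GeometryError("vanishing director")
    nr, npp, nz = nr / nn, npp / nn, nz / nn

    cosm = nr * Nm[0] + npp * Nm[1] + nz * Nm[2]
    sgn_mid = np.sign(np.mean(cosm))
    cosm = cosm * sgn_mid
    if np.any(cosm <= 1e-3):
        raise DegenerateDirectorError(
            "director nearly parallel to the mid-plane")

    # Tail length δ = δ0 √(1+t²) with the tilt measured against the
    # dividing-plane normal.  The relation is implicit (the dividing plane
    # is built with δ); it is resolved by one explicit correction step:
    # the tilt is evaluated on the surface offset at constant δ0 and the
    # offset is rebuilt once with the resulting δ field.  This keeps the
    # construction deterministic and smooth in the shape coefficients
    # (an open-ended fixed point is unstable near the stalk waist, where
    # the dividing-plane normal swings by ~90° across the mirror joint).
    # the projected tail-length deviation vanishes to first order at the
    # outer edge (x = 1), where tilt is zero by construction, so the offset
    # surface stays parallel there and the edge tilt invariant holds
    Sm = smoothing_projector(nx, 6, edge_flat=True)
    delta = np.full_like(cosm, patch.delta0)
    cosd = None
    for it in range(2):
        Qr = Pr + delta * nr
        Qp = Pp + delta * npp
        Qz = Pz + delta * nz
        e1 = (Dx @ Qr, Dx @ Qp, Dx @ Qz)
        e2 = _dphi_vec(Qr, Qp, Qz, Dphi)
        Ncr = _cross(e1, e2)
        area_vec = np.sqrt(Ncr[0] ** 2 + Ncr[1] ** 2 + Ncr[2] ** 2)
        if np.any(area_vec <= 1e-12):
            raise GeometryError("degenerate dividing-plane chart (folded element)",
                                badness=10.0)
        N = (Ncr[0] / area_vec, Ncr[1] / area_vec, Ncr[2] / area_vec)
        cosd = nr * N[0] + npp * N[1] + nz * N[2]
        sgn = np.sign(np.mean(cosd))
        N = (N[0] * sgn, N[1] * sgn, N[2] * sgn)
        cosd = cosd * sgn
        if it == 0:
            upd = patch.delta0 / np.maximum(cosd, 0.3) - patch.delta0
            # tail lengthening saturates smoothly at 1.6 δ0 (tilt ≈ 1.25):
            # equilibrium tilts stay below this, and the saturation keeps
            # strongly deformed trial shapes from folding their offset
            # surfaces while leaving the energy smooth in the coefficients
            d0 = patch.delta0
            delta = d0 + 0.6 * d0 * np.tanh((Sm @ upd) / (0.6 * d0))
    # orientation consistency: the dividing-plane normal (oriented along
    # the director) must agree with the mid-plane normal; a mean negative
    # overlap means the offset surface has passed through itself (e.g. an
    # inward offset exceeding the curvature radius)
    if strict and np.any(Qr < -1e-9):
        raise GeometryError(
            "dividing plane crosses the symmetry axis (offset exceeds the "
            "local curvature radius along the director)", badness=5.0)
    flip = (N[0] * Nm[0] + N[1] * Nm[1] + N[2] * Nm[2]) * sgn_mid
    if strict and np.mean(flip) < 0:
        raise GeometryError(
            "dividing plane is inverted (offset exceeds the local curvature "
            "radius along the director)", badness=5.0)
    if strict and np.any(cosd <= 2e-2):
        raise GeometryError(
            "dividing plane self-intersects (director crosses the surface "
            f"plane at x={xg[np.unravel_index(np.argmin(cosd), cosd.shape)[0]]:.3f})",
            badness=float(2e-2 - cosd.min()))

    t2 = 1.0 / np.maximum(cosd, 5e-2) ** 2 - 1.0

    g11 = _dot(e1, e1)
    g12 = _dot(e1, e2)
    g22 = _dot(e2, e2)
    detg = g11 * g22 - g12 ** 2

    d1n = (Dx @ nr, Dx @ npp, Dx @ nz)
    d2n = _dphi_vec(nr, npp, nz, Dphi)
    D11 = _dot(d1n, e1)
    D12 = _dot(d1n, e2)
    D21 = _dot(d2n, e1)
    D22 = _dot(d2n, e2)

    J = (g22 * D11 - g12 * (D12 + D21) + g11 * D22) / detg
    K = (D11 * D22 - D12 * D21) / detg

    dA = area_vec * (wx[:, None] * wphi[None, :])

    # smooth barrier against near-folded offsets (director approaching the
    # dividing-surface plane): keeps the energy landscape differentiable
    # where the hard self-intersection error would otherwise create cliffs
    soft = np.logaddexp(0.0, (0.12 - cosd) / 0.03)
    fold_penalty = float((50.0 * soft ** 2 * dA).sum())

    # tilt vectors extrapolated to the element ends (junction rings):
    # used to enforce tilt continuity across three-way junctions.  The
    # components are projected onto degree-10 polynomials first — raw
    # barycentric extrapolation of the boundary-layer fields is unstable
    # at moderate quadrature orders
    w0, w1 = endpoint_weights(nx)
    Sm_t = smoothing_projector(nx, min(10, nx - 2))
    cosd_s = np.maximum(cosd, 5e-2)
    tvec = (Sm_t @ (nr / cosd_s - N[0]), Sm_t @ (npp / cosd_s - N[1]),
            Sm_t @ (nz / cosd_s - N[2]))
    edges = {}
    for tag, w in (("edge0", w0), ("edge1", w1)):
        edges[tag] = {"t": np.stack([w @ c for c in tvec]),
                      "r": w @ Qr, "z": w @ Qz}

    out = {"J": J, "K": K, "t2": t2, "dA": dA, "area": float(dA.sum()),
           "delta": delta, "x": xg, "phi": phig, "fold_penalty": fold_penalty,
           "edge0": edges["edge0"], "edge1": edges["edge1"]}
    if full_output:
        out.update({"position": (Qr, Qp, Qz), "director": (nr, npp, nz),
                    "midplane": (Pr, Pp, Pz), "normal": N,
                    "tilt": (nr / cosd - N[0], npp / cosd - N[1], nz / cosd - N[2]),
                    "mid_e1": e1m, "mid_normal": Nm})
    return out


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a, b):
    return (a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0])


def _normalize(a):
    n = np.sqrt(_dot(a, a))
    return (a[0] / n, a[1] / n, a[2] / n)


# ---------------------------------------------------------------------------
# spec-level convenience operations
# ---------------------------------------------------------------------------

def splay_and_saddle(patch: MembranePatch, side: str, point,
                     nx: int = 32, nphi: int | None = None):
    """Splay J̃ and saddle splay K̃ of one leaflet at surface coordinates
    ``point = (x, phi)`` (interpolated from the quadrature grid)."""
    x0, phi0 = point
    if not (0.0 <= x0 <= 1.0):
        raise GeometryError(f"x={x0} outside the element domain [0, 1]")
    g = monolayer_grids(patch, side, nx=nx, nphi=nphi)
    iphi = 0
    if g["phi"].size > 1:
        iphi = int(np.argmin(np.abs(np.angle(np.exp(1j * (g["phi"] - phi0))))))
    J = np.interp(x0, g["x"], g["J"][:, iphi])
    K = np.interp(x0, g["x"], g["K"][:, iphi])
    return float(J), float(K)


def offset_dividing_plane(patch: MembranePatch, side: str, nx: int = 32,
                          nphi: int | None = None) -> list[SurfaceFrame]:
    """Sampled frames of one leaflet's dividing plane.

    Raises :class:`GeometryError` when the offset surface self-intersects
    (mid-plane curvature radius smaller than δ along the director).
    """
    g = monolayer_grids(patch, side, nx=nx, nphi=nphi, full_output=True)
    Qr, Qp, Qz = g["position"]
    N = g["normal"]
    frames = []
    for i in range(Qr.shape[0]):
        for j in range(Qr.shape[1]):
            phi = g["phi"][j]
            rot = np.array([[np.cos(phi), -np.sin(phi), 0.0],
                            [np.sin(phi), np.cos(phi), 0.0],
                            [0.0, 0.0, 1.0]])
            pos = rot @ np.array([Qr[i, j], Qp[i, j], Qz[i, j]])
            nrm = rot @ np.array([N[0][i, j], N[1][i, j], N[2][i, j]])
            frames.append(SurfaceFrame(position=pos, tangents=(None, None),
                                       normal=nrm, dA=float(g["dA"][i, j])))
    return frames
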