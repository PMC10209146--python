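"""Polynomial bases, collocation differentiation, and quadrature.

Shape fields are polynomials in a scaled radial coordinate x ∈ [0, 1]
(Chebyshev basis for conditioning), optionally carrying low-order Fourier
modes cos(2kφ) / sin(2kφ) in the azimuth for quarter-turn symmetric
configurations.  Boundary conditions are linear constraints on the
coefficients; each constrained polynomial therefore exposes a reduced set
of free parameters y with coeffs = N y + c_p(d), where N spans the null
space of the constraint matrix and c_p is a particular solution for the
current constraint values d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial import chebyshev as C
from scipy.linalg import null_space, lstsq


@lru_cache(maxsize=32)
def gauss_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights on [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def cheb_vander(x: np.ndarray, order: int, deriv: int = 0) -> np.ndarray:
    """Chebyshev-basis Vandermonde (domain [0,1]) or its derivative."""
    x = np.asarray(x, dtype=float)
    u = 2.0 * x - 1.0  # map to [-1, 1]
    n = order + 1
    V = np.zeros((x.size, n))
    for k in range(n):
        ck = np.zeros(n)
        ck[k] = 1.0
        dk = C.chebder(ck, deriv) if deriv else ck
        V[:, k] = C.chebval(u, dk) * (2.0 ** deriv)
    return V


@lru_cache(maxsize=32)
def gauss_diff_matrix(n: int) -> np.ndarray:
    """Cached differentiation matrix on the n-point Gauss grid of [0, 1]."""
    return diff_matrix(gauss_nodes(n)[0])


def diff_matrix(x: np.ndarray) -> np.ndarray:
    """Collocation differentiation matrix for arbitrary distinct nodes.

    Built from barycentric Lagrange weights; exact for polynomials of
    degree < len(x) and spectrally accurate for smooth functions.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    dx = x[:, None] - x[None, :]
    np.fill_diagonal(dx, 1.0)
    w = 1.0 / np.prod(dx, axis=1)
    D = (w[None, :] / w[:, None]) / dx
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -D.sum(axis=1))
    return D


@lru_cache(maxsize=32)
def endpoint_weights(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric interpolation rows evaluating nodal data on the n-point
    Gauss grid at x = 0 and x = 1 (spectrally accurate extrapolation)."""
    x, _ = gauss_nodes(n)
    dx = x[:, None] - x[None, :]
    np.fill_diagonal(dx, 1.0)
    w = 1.0 / np.prod(dx, axis=1)

    def row(x0):
        d = x0 - x
        r = w / d
        return r / r.sum()
    return row(0.0), row(1.0)


@lru_cache(maxsize=32)
def smoothing_projector(n: int, degree: int, edge_flat: bool = False) -> np.ndarray:
    """Least-squares projector of grid values on the n-point Gauss grid onto
    polynomials of the given degree (used to keep derived fields smooth in
    fixed-point iterations).  With ``edge_flat`` the projected field also
    vanishes with zero slope at x = 1 (basis weighted by (1−x)²)."""
    x, w = gauss_nodes(n)
    B = cheb_vander(x, degree)
    if edge_flat:
        B = B * ((1.0 - x) ** 2)[:, None]
    Bw = B * w[:, None]
    G = B.T @ Bw
    return B @ np.linalg.solve(G + 1e-12 * np.eye(G.shape[0]), Bw.T)


@lru_cache(maxsize=8)
def fourier_diff_matrix(n: int, period: float = 2.0 * np.pi) -> np.ndarray:
    """Spectral differentiation matrix on a uniform periodic grid."""
    if n == 1:
        return np.zeros((1, 1))
    if n % 2:
        raise ValueError("use an even number of azimuthal points")
    j = np.arange(n)
    diff = j[:, None] - j[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 0.5 * (-1.0) ** diff / np.tan(diff * np.pi / n)
    np.fill_diagonal(D, 0.0)
    return D * (2.0 * np.pi / period)


@dataclass
class ConstrainedPoly:
    """Polynomial of order M on [0, 1] with linear endpoint constraints.

    Parameters
    ----------
    order : polynomial order M (M+1 coefficients).
    constraints : list of (x0, deriv_order) pairs.  Constraint *values*
        are supplied at assembly time, so they may depend on scalar DOFs.
    """

    order: int
    constraints: list = field(default_factory=list)

    def __post_init__(self):
        n = self.order + 1
        if len(self.constraints) > n:
            raise ValueError("more constraints than coefficients")
        if self.constraints:
            rows = [cheb_vander(np.array([x0]), self.order, deriv=k)[0]
                    for (x0, k) in self.constraints]
            self.C = np.array(rows)
            self.N = null_space(self.C)
            # particular solution: the lowest-degree (Hermite) interpolant of
            # the constraint values — the min-coefficient-norm (pseudo-inverse)
            # choice oscillates strongly in the Chebyshev basis and would make
            # zero free coefficients correspond to a wiggly field
            k = len(self.constraints)
            head = self.C[:, :k]
            self._Cpinv = np.zeros((n, k))
            try:
                self._Cpinv[:k, :] = np.linalg.solve(head, np.eye(k))
            except np.linalg.LinAlgError:
                self._Cpinv = np.linalg.pinv(self.C)
        else:
            self.C = np.zeros((0, n))
            self.N = np.eye(n)
            self._Cpinv = np.zeros((n, 0))

    @property
    def n_free(self) -> int:
        return self.N.shape[1]

    def coeffs(self, y: np.ndarray, values=()) -> np.ndarray:
        """Assemble full coefficient vector from free params and BC values."""
        y = np.asarray(y, dtype=float)
        c = self.N @ y
        if len(self.constraints):
            c = c + self._Cpinv @ np.asarray(values, dtype=float)
        return c

    def project(self, coeffs: np.ndarray, values=()) -> np.ndarray:
        """Free parameters whose assembled polynomial is closest (in
        coefficient space) to ``coeffs`` under the current constraint
        values (null-space columns are orthonormal)."""
        c = np.asarray(coeffs, dtype=float)
        if len(self.constraints):
            c = c - self._Cpinv @ np.asarray(values, dtype=float)
        return self.N.T @ c

    def fit(self, f, values=(), n_sample: int = 64) -> np.ndarray:
        """Least-squares free parameters approximating callable f(x) subject
        to the constraints (used to build initial shapes)."""
        xs = np.linspace(0.0, 1.0, n_sample)
        B = cheb_vander(xs, self.order)
        target = np.asarray([f(x) for x in xs], dtype=float)
        if len(self.constraints):
            base = self._Cpinv @ np.asarray(values, dtype=float)
            target = target - B @ base
        A = B @ self.N
        y, *_ = lstsq(A, target)
        return y


def poly_eval(coeffs: np.ndarray, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Evaluate a Chebyshev-basis polynomial (domain [0,1]) or derivative."""
    u = 2.0 * np.asarray(x, dtype=float) - 1.0
    c = np.asarray(coeffs, dtype=float)
    if deriv:
        c = C.chebder(c, deriv) * (2.0 ** deriv)
    return C.chebval(u, c)
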