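"""Global energy minimization over shape coefficients and boundary DOFs.

The stalk and diaphragm barriers are constrained minima of the total
elastic energy:

    E_stalk = min U_elastic | ρ_D = 0  −  U0_up − U0_down
    E_HD    = min U_elastic            −  U0_up − U0_down

with U0 the closed-form prefusion energies.  Minimization operates on the
polynomial coefficients and scalar boundary DOFs jointly, with multi-start
from seeded perturbations of a heuristic initial shape to approach the
global minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize as sopt

from .configurations import (CompartmentSpec, FusionSiteState,
                             build_diaphragm_configuration,
                             build_stalk_configuration)
from .elastic import EnergyBreakdown, MaterialParams, prefusion_energy, total_energy

__all__ = ["MinimizerOptions", "EquilibriumResult", "minimize",
           "stalk_energy", "diaphragm_energy", "staged_minimize",
           "NonConvergenceError"]


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, last_result=None):
        super().__init__(msg)
        self.last_result = last_result


@dataclass
class MinimizerOptions:
    """Options for the shape minimizer."""

    order: int = 8                 # polynomial expansion order M
    n_starts: int = 5
    seed: int = 0
    method: str = "lbfgs"          # "lbfgs" | "gradient_descent"
    max_iter: int = 1500
    gtol: float = 1e-6
    ftol: float = 1e-11
    fd_step: float = 1e-6
    perturbation: float = 0.08     # multi-start restart scale
    nx: int = 32                   # radial quadrature points

    def __post_init__(self):
        if self.order < 3:
            raise ValueError("polynomial order must be at least 3")
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        if self.ftol <= 0 or self.gtol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class EquilibriumResult:
    """Converged fusion-site state and its energetics."""

    state: FusionSiteState
    breakdown: EnergyBreakdown
    energy: float                  # absolute elastic energy U (k_BT)
    barrier: float                 # E_stalk or E_HD (k_BT, vs prefusion)
    per_start_energies: list = field(default_factory=list)
    iterations: int = 0
    grad_norm: float = float("nan")
    converged: bool = True
    seed: int = 0

    def summary(self) -> dict:
        s = {k: v for k, v in self.state.scalars.items()
             if isinstance(v, (int, float, str))}
        return {
            "energy_kBT": self.energy,
            "barrier_kBT": self.barrier,
            "per_start_energies_kBT": list(map(float, self.per_start_energies)),
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
            "converged": self.converged,
            "seed": self.seed,
            "dofs": s,
            "breakdown": self.breakdown.to_dict(),
        }


def _fd_gradient(f, x, f0, step):
    g = np.zeros_like(x)
    for i in range(x.size):
        xp = x.copy()
        xp[i] += step
        g[i] = (f(xp) - f0) / step
    return g


def _gradient_descent(f, x0, bounds, opts: MinimizerOptions):
    """Projected gradient descent with Armijo backtracking line search.

    Accepted iterates have non-increasing energy by construction.
    """
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fx = f(x)
    step = 1e-3
    n_eval = 0
    history = [fx]
    for it in range(opts.max_iter):
        g = _fd_gradient(f, x, fx, opts.fd_step)
        gnorm = float(np.linalg.norm(g))
        if gnorm < opts.gtol:
            break
        step = min(step * 2.0, 1.0 / max(gnorm, 1e-12))
        accepted = False
        for _ in range(40):
            xn = np.clip(x - step * g, lo, hi)
            fn = f(xn)
            n_eval += 1
            if fn <= fx - 1e-4 * float(g @ (x - xn)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = abs(fx - fn) / max(1.0, abs(fx))
        x, fx = xn, fn
        history.append(fx)
        if rel < opts.ftol:
            break
    return x, fx, it + 1, gnorm, history


def _single_minimize(prob, x0, opts: MinimizerOptions):
    bounds = prob.bounds()
    best = {"x": np.asarray(x0, dtype=float).copy(), "f": np.inf}

    def f(x):
        v = prob.energy(x)
        if v < best["f"]:
            best["f"] = v
            best["x"] = np.asarray(x, dtype=float).copy()
        return v

    if opts.method == "gradient_descent":
        x, fx, nit, gnorm, hist = _gradient_descent(f, x0, bounds, opts)
        return x, fx, nit, gnorm, hist
    res = sopt.minimize(
        f, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": opts.max_iter, "ftol": opts.ftol,
                 "gtol": opts.gtol, "eps": opts.fd_step, "maxcor": 30})
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    # L-BFGS-B reports the last iterate; on abnormal termination near a
    # penalised region the best visited point is the meaningful result
    if best["f"] < float(res.fun):
        return best["x"], best["f"], int(res.nit), gnorm, None
    return res.x, float(res.fun), int(res.nit), gnorm, None


def minimize(config: FusionSiteState, params: MaterialParams | None = None,
             options: MinimizerOptions | None = None) -> EquilibriumResult:
    """Minimize the elastic energy of a built fusion-site configuration.

    Multi-start: the heuristic initial vector plus ``n_starts − 1`` seeded
    Gaussian perturbations; the lowest final energy wins (ties broken by
    gradient norm).
    """
    opts = options or MinimizerOptions()
    prob = config.problem
    if prob is None:
        raise ValueError("configuration carries no attached problem")
    params = params or prob.params
    prob.params = params
    x0 = config.dof_vector
    if x0 is None:
        x0 = prob.initial_vector()
    rng = np.random.default_rng(opts.seed)
    bounds = prob.bounds()
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])

    starts = [np.asarray(x0, dtype=float)]
    for _ in range(opts.n_starts - 1):
        sig = opts.perturbation * np.maximum(0.3, np.abs(x0))
        starts.append(np.clip(x0 + rng.normal(size=x0.size) * sig, lo, hi))

    # staged multi-start: cheap exploration of every start, then full
    # polish of the most promising iterates
    energies = []
    explored = []
    if len(starts) > 1:
        import copy
        short = copy.copy(opts)
        short.max_iter = min(300, opts.max_iter)
        for xs in starts:
            x, fx, nit, gnorm, _ = _single_minimize(prob, xs, short)
            explored.append((fx, gnorm, x, nit))
        explored.sort(key=lambda c: c[0])
        polish = [c[2] for c in explored[:2]]
    else:
        polish = starts
    best = None
    for xs in polish:
        x, fx, nit, gnorm, _ = _single_minimize(prob, xs, opts)
        energies.append(fx)
        cand = (fx, gnorm, x, nit)
        if best is None or fx < best[0] - 1e-6 or \
                (abs(fx - best[0]) <= 1e-6 and gnorm < best[1]):
            best = cand
    fx, gnorm, x, nit = best
    if fx >= 1e5:
        raise NonConvergenceError("all starts ended in infeasible geometry")
    state = prob.assemble(x)
    bd = total_energy(state, params, nx=getattr(prob, "nx", opts.nx),
                      nphi=state.nphi)
    return EquilibriumResult(state=state, breakdown=bd, energy=bd.total,
                             barrier=np.nan, per_start_energies=energies,
                             iterations=nit, grad_norm=gnorm, seed=opts.seed)


def _finish(res: EquilibriumResult, up, down, params) -> EquilibriumResult:
    U0 = prefusion_energy(up, params) + prefusion_energy(down, params)
    res.barrier = res.energy - U0
    res.breakdown.reference = U0
    return res


def _clip_to_bounds(v, bounds):
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    return np.clip(np.asarray(v, dtype=float), lo, hi)


def _mirror_twin(comp: CompartmentSpec) -> CompartmentSpec:
    return CompartmentSpec(kind=comp.kind, R_c=comp.R_c, L=comp.L,
                           fixed_volume=comp.fixed_volume,
                           tension_reservoir=comp.tension_reservoir)


def stalk_energy(up: CompartmentSpec, down: CompartmentSpec,
                 params: MaterialParams, regime: str = "reservoir",
                 options: MinimizerOptions | None = None,
                 warm_from: EquilibriumResult | None = None) -> EquilibriumResult:
    """Equilibrium hemifusion stalk (ρ_D = 0) and its formation energy.

    Asymmetric pairings (e.g. sphere-flat) are warm-started from the two
    corresponding symmetric solutions, mirroring the lower membrane.
    """
    opts = options or MinimizerOptions()
    config = build_stalk_configuration(up, down, params, regime=regime,
                                       order=opts.order, nx=opts.nx)
    prob = config.problem
    if warm_from is not None:
        v = warm_from.state.dof_vector
        if v is not None and v.size == config.dof_vector.size:
            config = prob.assemble(_clip_to_bounds(v, prob.bounds()))
    elif getattr(prob, "mirror", True) is False and hasattr(prob, "compose_from_mirror"):
        sub = MinimizerOptions(order=opts.order, n_starts=max(2, opts.n_starts - 2),
                               seed=opts.seed, nx=opts.nx, max_iter=opts.max_iter)
        r_up = stalk_energy(prob.up, _mirror_twin(prob.up), params, regime, sub)
        r_dn = stalk_energy(prob.down, _mirror_twin(prob.down), params, regime, sub)
        try:
            vec = prob.compose_from_mirror(r_up.state, r_dn.state)
            if prob.energy(vec) < 5e4:
                config = prob.assemble(vec)
        except Exception:
            pass
    res = minimize(config, params, opts)
    return _finish(res, up, down, params)


def _pin_release(config, params, opts: MinimizerOptions,
                 pin: str = "rho_D",
                 ladder=None) -> EquilibriumResult:
    """Diaphragm minimization by continuation: the shape is relaxed at a
    short ladder of pinned rim radii (chained warm starts), then the rim
    radius is released from the best rung.  This reliably reaches the
    equilibrium branch, which free minimization frequently misses among
    the basins of the strongly coupled rim DOFs."""
    prob = config.problem
    lo, hi = prob.dofs.bound(pin)
    vec = np.asarray(config.dof_vector, dtype=float).copy()
    if ladder is None:
        # relax at the configuration's own rim radius before releasing
        ladder = (float(prob.dofs.get(vec, pin)),)
    import copy
    short = copy.copy(opts)
    short.max_iter = min(800, opts.max_iter)
    best = None
    for k, r in enumerate(ladder):
        r = min(hi, max(lo, r))
        prob.dofs.set(vec, pin, r)
        token = prob.dofs.pin(pin, r)
        try:
            rung = copy.copy(short)
            rung.n_starts = opts.n_starts if k == 0 else 1
            res = minimize(prob.assemble(vec), params, rung)
        except NonConvergenceError:
            prob.dofs.unpin(token)
            continue
        finally:
            try:
                prob.dofs.unpin(token)
            except Exception:
                pass
        vec = res.state.dof_vector.copy()
        if best is None or res.energy < best.energy:
            best = res
    if best is None:
        raise NonConvergenceError("all pinned rim relaxations failed")
    cfg2 = prob.assemble(best.state.dof_vector)
    opts2 = MinimizerOptions(order=opts.order, n_starts=2, seed=opts.seed,
                             nx=opts.nx, max_iter=opts.max_iter,
                             perturbation=0.04)
    return minimize(cfg2, params, opts2)


def staged_minimize(config, params, opts: MinimizerOptions,
                    freeze_tag: str = "2") -> EquilibriumResult:
    """Two-stage minimization for quarter-turn problems: the azimuthal
    (cos 2φ / sin 2φ) degrees of freedom are frozen at their initial
    values while the axisymmetric content relaxes, then everything is
    released.  Cuts the effective dimensionality of the hardest stage."""
    import copy
    prob = config.problem
    x0 = np.asarray(config.dof_vector, dtype=float)
    frozen = np.zeros(x0.size, dtype=bool)
    for name, size, lo, hi, off, scale in prob.dofs.blocks:
        if freeze_tag in name:
            frozen[off:off + size] = True
    base_bounds = prob.bounds()

    def frozen_bounds():
        return [(x0[i], x0[i]) if frozen[i] else b
                for i, b in enumerate(base_bounds)]

    orig = prob.bounds
    prob.bounds = frozen_bounds
    try:
        stage1 = minimize(config, params, copy.copy(opts))
    finally:
        prob.bounds = orig
    cfg2 = prob.assemble(stage1.state.dof_vector)
    opts2 = copy.copy(opts)
    opts2.n_starts = 2
    opts2.perturbation = 0.03
    return minimize(cfg2, params, opts2)


def diaphragm_energy(up: CompartmentSpec, down: CompartmentSpec,
                     params: MaterialParams, regime: str = "reservoir",
                     options: MinimizerOptions | None = None,
                     initial: FusionSiteState | None = None,
                     warm_from: EquilibriumResult | None = None) -> EquilibriumResult:
    """Equilibrium hemifusion diaphragm (free rim) and its formation energy."""
    opts = options or MinimizerOptions()
    config = build_diaphragm_configuration(up, down, params, regime=regime,
                                           initial=initial, order=opts.order,
                                           nx=opts.nx)
    prob = config.problem
    if warm_from is not None:
        v = warm_from.state.dof_vector
        if v is not None and v.size == config.dof_vector.size:
            config = prob.assemble(_clip_to_bounds(v, prob.bounds()))
    elif (initial is None and getattr(prob, "mirror", True) is False
          and hasattr(prob, "compose_from_mirror")):
        sub = MinimizerOptions(order=opts.order, n_starts=max(2, opts.n_starts - 2),
                               seed=opts.seed, nx=opts.nx, max_iter=opts.max_iter)
        r_up = diaphragm_energy(prob.up, _mirror_twin(prob.up), params, regime, sub)
        r_dn = diaphragm_energy(prob.down, _mirror_twin(prob.down), params, regime, sub)
        try:
            vec = prob.compose_from_mirror(r_up.state, r_dn.state)
            if prob.energy(vec) < 5e4:
                config = prob.assemble(vec)
        except Exception:
            pass
    res = _pin_release(config, params, opts, ladder=(2.0, 3.0))
    return _finish(res, up, down, params)
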