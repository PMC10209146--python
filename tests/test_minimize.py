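"""Shape minimizer: descent properties, gradient checks, reproducibility.

The heavier equilibrium computations (paper-scale barriers) live in
test_acceptance.py; here the minimizer itself is exercised on reduced
problem sizes.
"""

import numpy as np
import pytest

from hemifusion import (CompartmentSpec, MaterialParams, MinimizerOptions,
                        build_stalk_configuration, minimize, stalk_energy)
from hemifusion.minimize import _fd_gradient, _gradient_descent


@pytest.fixture(scope="module")
def small_opts():
    return MinimizerOptions(n_starts=1, max_iter=150, order=6, nx=24)


@pytest.fixture(scope="module")
def ff_problem(flat, params):
    cfg = build_stalk_configuration(flat, flat, params, order=6, nx=24)
    return cfg


class TestOptionsValidation:
    def test_order_floor(self):
        with pytest.raises(ValueError):
            MinimizerOptions(order=2)

    def test_positive_tolerances(self):
        with pytest.raises(ValueError):
            MinimizerOptions(ftol=0.0)

    def test_at_least_one_start(self):
        with pytest.raises(ValueError):
            MinimizerOptions(n_starts=0)


class TestGradients:
    def test_finite_difference_gradient_consistency(self, ff_problem):
        """Central vs forward finite differences agree at a feasible point
        (the solver's forward-difference gradients are trustworthy)."""
        prob = ff_problem.problem
        x = ff_problem.dof_vector
        f0 = prob.energy(x)
        g_fwd = _fd_gradient(prob.energy, x, f0, 1e-6)
        g_ctr = np.zeros_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += 1e-5
            xm[i] -= 1e-5
            g_ctr[i] = (prob.energy(xp) - prob.energy(xm)) / 2e-5
        big = np.abs(g_ctr) > 1e-3
        assert np.allclose(g_fwd[big], g_ctr[big], rtol=2e-2)


class TestGradientDescent:
    def test_monotone_descent(self, ff_problem, params):
        """Accepted gradient-descent iterates never increase the energy."""
        prob = ff_problem.problem
        opts = MinimizerOptions(n_starts=1, max_iter=40,
                                method="gradient_descent")
        x, fx, nit, gnorm, hist = _gradient_descent(
            prob.energy, ff_problem.dof_vector, prob.bounds(), opts)
        assert len(hist) > 3
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_descent_reduces_energy_substantially(self, ff_problem):
        prob = ff_problem.problem
        opts = MinimizerOptions(n_starts=1, max_iter=40,
                                method="gradient_descent")
        x, fx, *_ = _gradient_descent(prob.energy, ff_problem.dof_vector,
                                      prob.bounds(), opts)
        assert fx < prob.energy(ff_problem.dof_vector)


class TestMinimize:
    def test_seeded_runs_are_bitwise_reproducible(self, flat, params):
        opts = MinimizerOptions(n_starts=2, max_iter=200, order=6, nx=24,
                                seed=3)
        r1 = stalk_energy(flat, flat, params, "reservoir", opts)
        r2 = stalk_energy(flat, flat, params, "reservoir", opts)
        assert r1.barrier == r2.barrier
        assert np.array_equal(r1.state.dof_vector, r2.state.dof_vector)

    def test_multistart_consistency_across_seeds(self, flat, params):
        """Different seeds converge to the same flat-flat stalk minimum."""
        vals = []
        for seed in (0, 1):
            opts = MinimizerOptions(n_starts=3, seed=seed)
            vals.append(stalk_energy(flat, flat, params, "reservoir",
                                     opts).barrier)
        assert abs(vals[0] - vals[1]) < 0.5

    def test_result_reports_best_of_starts(self, flat, params, small_opts):
        r = stalk_energy(flat, flat, params, "reservoir",
                         MinimizerOptions(n_starts=2, max_iter=200,
                                          order=6, nx=24))
        assert r.energy <= min(r.per_start_energies) + 1e-9

    def test_missing_problem_rejected(self, params):
        from hemifusion import FusionSiteState
        empty = FusionSiteState(patches={}, monolayers=[], units={})
        with pytest.raises(ValueError):
            minimize(empty, params)

    def test_converged_state_satisfies_junction_continuity(self, flat, params):
        r = stalk_energy(flat, flat, params, "reservoir",
                         MinimizerOptions(n_starts=2))
        assert r.breakdown.junction_tilt_mismatch < 0.05
        assert r.breakdown.junction_penalty < 1.0
        assert r.breakdown.fold_penalty < 1.0
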