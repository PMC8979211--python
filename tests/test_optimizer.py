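import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import brentq

from geudplan.dose import DoseCorrelationMatrix, MixedFieldTable, PhotonResponse, physical_dose
from geudplan.objectives import (
    DoseEngines,
    GEUDObjective,
    MaxDoseObjective,
    PlanObjectives,
    TargetObjective,
    cost_gradient,
    total_cost,
)
from geudplan.optimizer import (
    NonDescentError,
    OptimizerConfig,
    cgfr_direction,
    optimize,
    preoptimize,
    sd_direction,
    stepsize_biological,
    stepsize_physical,
)
from geudplan.phantom import VOIMask

from conftest import random_instance


def _single_voxel_problem(d=0.5, D_pre=3.0):
    matrix = DoseCorrelationMatrix(d=sp.csr_matrix(np.array([[d]])))
    target = VOIMask("t", "target", np.array([0]))
    plan = PlanObjectives(items=((target, TargetObjective(D_pre)),), dose_model="physical")
    return matrix, plan


class TestPreoptimize:
    def test_exact_single_spot_scaling(self):
        matrix, plan = _single_voxel_problem()
        np.testing.assert_allclose(preoptimize(matrix, plan), [6.0])

    def test_doubling_prescription_doubles_weights(self, single_gland):
        phantom, matrix, _ = single_gland
        p1 = PlanObjectives(items=((phantom.target, TargetObjective(3.0)),), dose_model="physical")
        p2 = PlanObjectives(items=((phantom.target, TargetObjective(6.0)),), dose_model="physical")
        np.testing.assert_allclose(preoptimize(matrix, p2), 2 * preoptimize(matrix, p1))

    def test_mean_target_dose_equals_prescription(self, single_gland):
        phantom, matrix, _ = single_gland
        plan = PlanObjectives(items=((phantom.target, TargetObjective(3.0)),), dose_model="physical")
        N0 = preoptimize(matrix, plan)
        mean = physical_dose(matrix, N0)[phantom.target.voxel_indices].mean()
        assert mean == pytest.approx(3.0, abs=1e-10)


class TestDirections:
    def test_sd_negates_gradient(self):
        np.testing.assert_array_equal(sd_direction(np.array([1.0, -2.0])), [-1.0, 2.0])
        np.testing.assert_array_equal(sd_direction(np.zeros(3)), np.zeros(3))

    def test_cgfr_initializes_with_steepest_descent(self):
        g = np.array([1.0, 2.0])
        np.testing.assert_array_equal(cgfr_direction(g, None, None, 0, 25), -g)

    def test_cgfr_unit_beta_accumulates(self):
        g = np.array([1.0, -1.0])
        h = cgfr_direction(g, g, -g, 3, 25)
        np.testing.assert_allclose(h, -2 * g)

    def test_cgfr_periodic_restart(self):
        g = np.array([1.0, -1.0])
        h = cgfr_direction(g, g, -g, 25, 25)
        np.testing.assert_array_equal(h, -g)

    def test_cgfr_restart_on_vanished_previous_gradient(self):
        g = np.array([1.0, 0.0])
        np.testing.assert_array_equal(cgfr_direction(g, np.zeros(2), -g, 3, 25), -g)

    def test_cgfr_descent_guarantee(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g_new, g_old, h_old = rng.normal(size=(3, 6))
            h = cgfr_direction(g_new, g_old, h_old, int(rng.integers(1, 20)), 25)
            assert np.dot(h, g_new) < 0 or np.linalg.norm(g_new) == 0


class TestStepsizePhysical:
    def test_worked_single_voxel_step(self):
        # D = 2, D_pre = 3, unit dose change per unit mu -> mu = 1
        matrix, plan = _single_voxel_problem(d=1.0)
        N = np.array([2.0])
        h = np.array([1.0])
        assert stepsize_physical(N, h, plan, matrix, mode="analytic") == pytest.approx(1.0)

    def test_zero_at_optimum(self):
        matrix, plan = _single_voxel_problem(d=0.5)
        g = cost_gradient(np.array([6.0]), plan, DoseEngines(matrix=matrix))
        np.testing.assert_array_equal(g, 0.0)
        assert stepsize_physical(np.array([6.0]), -g, plan, matrix) == 0.0

    def test_non_descent_direction_rejected(self):
        matrix, plan = _single_voxel_problem(d=0.5)
        g = cost_gradient(np.array([1.0]), plan, DoseEngines(matrix=matrix))
        with pytest.raises(NonDescentError):
            stepsize_physical(np.array([1.0]), +g, plan, matrix, grad=g)

    @pytest.mark.parametrize("seed", range(10))
    def test_analytic_matches_bisection_root(self, seed):
        """Frozen-Heaviside closed form vs a numerical root of dchi2/dmu."""
        matrix, _, tgt, oar, rng = random_instance(seed)
        w_oar, g0 = 5.0, 0.3
        plan = PlanObjectives(
            items=((tgt, TargetObjective(2.0)), (oar, GEUDObjective(g0, a=1, w=w_oar))),
            dose_model="physical",
        )
        engines = DoseEngines(matrix=matrix)
        N = rng.uniform(0.5, 2.0, matrix.n_spots)
        g = cost_gradient(N, plan, engines)
        h = -g
        mu_closed = stepsize_physical(N, h, plan, matrix, mode="analytic", grad=g)
        D0 = matrix.d @ N
        S = matrix.d @ h
        active = D0[oar.voxel_indices].mean() > g0

        def frozen_cost(mu):
            D = D0 + mu * S
            r = 2.0 - D[tgt.voxel_indices]
            c = np.sum(r * r) / (0.025 * 2.0) ** 2
            if active:
                c += w_oar**2 * (g0 - D[oar.voxel_indices].mean()) ** 2 / (0.025 * g0) ** 2
            return c

        eps = 1e-7
        mu_root = brentq(
            lambda mu: (frozen_cost(mu + eps) - frozen_cost(mu - eps)) / (2 * eps),
            0.0,
            4 * mu_closed + 1.0,
            xtol=1e-15,
        )
        assert mu_closed == pytest.approx(mu_root, rel=1e-6)

    def test_backtracking_mode_decreases_cost(self):
        matrix, _, tgt, oar, rng = random_instance(41)
        plan = PlanObjectives(
            items=((tgt, TargetObjective(2.0)), (oar, GEUDObjective(0.3, a=5, w=5.0))),
            dose_model="physical",
        )
        engines = DoseEngines(matrix=matrix)
        N = rng.uniform(0.5, 2.0, matrix.n_spots)
        g = cost_gradient(N, plan, engines)
        mu = stepsize_physical(N, -g, plan, matrix, mode="backtracking", grad=g)
        assert mu > 0
        assert total_cost(np.maximum(N - mu * g, 0), plan, engines) < total_cost(N, plan, engines)


class TestStepsizeBiological:
    def test_damping_factor_applied(self):
        matrix, table, tgt, oar, rng = random_instance(43)
        plan = PlanObjectives(items=((tgt, TargetObjective(2.0)),), dose_model="biological")
        engines = DoseEngines(matrix=matrix, table=table)
        N = rng.uniform(0.5, 2.0, matrix.n_spots)
        g = cost_gradient(N, plan, engines)
        h = -g
        mu_half, halv, ok = stepsize_biological(
            N, h, plan, engines, OptimizerConfig(f_damping=0.5), grad=g
        )
        mu_full, _, _ = stepsize_biological(
            N, h, plan, engines, OptimizerConfig(f_damping=1.0), grad=g
        )
        assert ok and halv == 0
        assert mu_half == pytest.approx(0.5 * mu_full)

    def test_photon_equivalent_tables_always_decrease(self):
        matrix, _, tgt, oar, rng = random_instance(47)
        alpha = matrix.d.copy()
        alpha.data = np.full(matrix.d.nnz, 0.1)
        sb = matrix.d.copy()
        sb.data = np.full(matrix.d.nnz, np.sqrt(0.05))
        table = MixedFieldTable(alpha=alpha, sqrt_beta=sb, photon=PhotonResponse(0.1, 0.05, 30.0))
        plan = PlanObjectives(items=((tgt, TargetObjective(2.0)),), dose_model="biological")
        engines = DoseEngines(matrix=matrix, table=table)
        N = rng.uniform(0.2, 0.8, matrix.n_spots)
        g = cost_gradient(N, plan, engines)
        mu, halv, ok = stepsize_biological(
            N, -g, plan, engines, OptimizerConfig(f_damping=1.0), grad=g
        )
        assert ok and halv == 0

    def test_safeguard_engages_on_strongly_nonlinear_case(self):
        # sqrt(beta_ij) >> sqrt(beta_x): the RBE-weighted dose is strongly
        # convex in N, the undamped linearized step overshoots, and the
        # halving safeguard must engage while preserving monotone descent
        d = sp.csr_matrix(np.array([[1.0]]))
        matrix = DoseCorrelationMatrix(d=d)
        alpha = d.copy()
        alpha.data = np.array([0.1])
        sb = d.copy()
        sb.data = np.array([5.0])
        table = MixedFieldTable(alpha=alpha, sqrt_beta=sb, photon=PhotonResponse(0.1, 0.05, 30.0))
        tgt = VOIMask("t", "target", np.array([0]))
        plan = PlanObjectives(items=((tgt, TargetObjective(3.0)),), dose_model="biological")
        state = optimize(
            plan,
            matrix,
            table,
            OptimizerConfig(algorithm="sd", f_damping=1.0, max_iter=50),
            N0=np.array([1e-3]),
        )
        accepted = [r for r in state.history if r.accepted]
        assert sum(r.halvings for r in accepted) >= 1
        costs = [r.cost for r in accepted]
        assert all(a > b for a, b in zip(costs, costs[1:]))


class TestOptimize:
    def test_single_spot_converges_to_exact_solution(self):
        matrix, plan = _single_voxel_problem(d=0.5, D_pre=3.0)
        state = optimize(
            plan,
            matrix,
            None,
            OptimizerConfig(algorithm="sd", stepsize_mode="analytic"),
            N0=np.array([1.0]),
        )
        assert state.N[0] == pytest.approx(6.0, abs=1e-4)
        assert state.converged

    @pytest.mark.parametrize("algorithm", ["sd", "cgfr"])
    @pytest.mark.parametrize("model", ["physical", "biological"])
    def test_monotone_descent_on_accepted_iterations(self, single_gland, algorithm, model):
        phantom, matrix, table = single_gland
        plan = PlanObjectives(
            items=(
                (phantom.target, TargetObjective(3.0)),
                (phantom.voi("gland_right"), GEUDObjective(0.5, a=1, w=20.0)),
            ),
            dose_model=model,
        )
        state = optimize(plan, matrix, table, OptimizerConfig(algorithm=algorithm, max_iter=60))
        costs = [r.cost for r in state.history if r.accepted]
        assert len(costs) > 5
        assert all(a > b for a, b in zip(costs, costs[1:]))

    def test_projection_keeps_particles_above_floor(self, single_gland):
        phantom, matrix, table = single_gland
        plan = PlanObjectives(
            items=(
                (phantom.target, TargetObjective(3.0)),
                (phantom.voi("gland_right"), GEUDObjective(0.4, a=1, w=50.0)),
            ),
            dose_model="physical",
        )
        floor = 1e-3
        state = optimize(plan, matrix, table, OptimizerConfig(max_iter=40, N_min=floor))
        assert state.N.min() >= floor - 1e-15

    def test_sd_and_cgfr_agree_on_convex_problem(self, single_gland):
        phantom, matrix, _ = single_gland
        plan = PlanObjectives(items=((phantom.target, TargetObjective(3.0)),), dose_model="physical")
        cfg = dict(max_iter=2000, rel_tol=1e-5, stepsize_mode="analytic")
        sd = optimize(plan, matrix, None, OptimizerConfig(algorithm="sd", **cfg))
        cg = optimize(plan, matrix, None, OptimizerConfig(algorithm="cgfr", **cfg))
        assert sd.converged and cg.converged
        assert abs(sd.cost - cg.cost) / max(sd.cost, cg.cost) < 0.01
        assert cg.k <= sd.k
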