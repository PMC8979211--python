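"""Line-search minimization of the plan cost over particle numbers.

Iterates ``N_{k+1} = clamp(N_k + mu_k h_k, N_min)`` with the direction
given by steepest descent (SD) or the Fletcher-Reeves conjugate-gradient
rule (CGFR, restarted periodically and on non-descent), and the stepsize
from the closed-form root of ``d chi^2 / d mu = 0`` with the one-sided
Heaviside sets frozen at mu = 0. That root is exact when every term is
linear in mu (physical dose, gEUD exponents a = 1); for a != 1 the gEUD
response is linearized along the search direction (its exact directional
derivative), and a backtracking Armijo search is available as a purely
numerical alternative. Biological optimization damps the physical step by
a factor f (default 0.5) to absorb the RBE non-linearity.

Every proposed step is safeguarded: if the cost does not decrease at the
proposed mu (a Heaviside crossed, the linearization overshot, or the RBE
curvature bit), mu is halved up to 20 times; a step that still fails is
rejected, and five consecutive rejections abort the run. Accepted
iterations therefore form a strictly decreasing cost sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dose import physical_dose
from .objectives import (
    DoseEngines,
    GEUDObjective,
    MaxDoseObjective,
    PlanObjectives,
    TargetGEUDObjective,
    TargetObjective,
    _geud_dose_coeff,
    cost_gradient,
    total_cost,
    total_cost_from_dose,
    voxel_cost_coefficients,
)
from .metrics import compute_geud

__all__ = [
    "OptimizerConfig",
    "IterationRecord",
    "OptimizerState",
    "NonDescentError",
    "preoptimize",
    "sd_direction",
    "cgfr_direction",
    "stepsize_physical",
    "stepsize_biological",
    "optimize",
]

_MAX_HALVINGS = 20
_MAX_REJECTS = 5
_CONVERGED_STREAK = 3


class NonDescentError(RuntimeError):
    """Raised when a stepsize is requested along a non-descent direction."""


@dataclass(frozen=True)
class OptimizerConfig:
    algorithm: str = "cgfr"  # "sd" | "cgfr"
    max_iter: int = 500
    rel_tol: float = 1e-5
    f_damping: float = 0.5
    N_min: float = 0.0
    restart_period: int = 25
    stepsize_mode: str = "linearized"  # "analytic" | "linearized" | "backtracking"

    def __post_init__(self) -> None:
        if self.algorithm not in ("sd", "cgfr"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not (0 < self.f_damping <= 1):
            raise ValueError("f_damping must be in (0, 1]")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.stepsize_mode not in ("analytic", "linearized", "backtracking"):
            raise ValueError(f"unknown stepsize mode {self.stepsize_mode!r}")


@dataclass
class IterationRecord:
    k: int
    cost: float
    stepsize: float
    grad_norm: float
    accepted: bool
    halvings: int = 0


@dataclass
class OptimizerState:
    k: int
    N: np.ndarray
    cost: float
    grad: np.ndarray
    history: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    aborted: bool = False


def preoptimize(matrix, plan: PlanObjectives, N_min: float = 0.0) -> np.ndarray:
    """Uniform spot weights scaled so the mean physical target dose equals
    the prescription (for a target-gEUD plan: the midpoint of the min/max
    prescriptions)."""
    voi, obj = plan.target_item
    if isinstance(obj, TargetObjective):
        D_pre = obj.D_pre
    else:
        D_pre = 0.5 * (obj.gEUD_0_min + obj.gEUD_0_max)
    ones = np.ones(matrix.n_spots)
    mean_dose = physical_dose(matrix, ones)[voi.voxel_indices].mean()
    if mean_dose <= 0:
        raise ValueError("no spot reaches the target")
    return np.maximum(ones * (D_pre / mean_dose), N_min)


def sd_direction(grad: np.ndarray) -> np.ndarray:
    """Steepest descent: h = -grad."""
    return -np.asarray(grad, dtype=float)


def cgfr_direction(
    grad_new: np.ndarray,
    grad_old: np.ndarray | None,
    h_old: np.ndarray | None,
    k: int,
    restart_period: int,
) -> np.ndarray:
    """Fletcher-Reeves conjugate direction with restarts.

    beta = |g_new|^2 / |g_old|^2; resets to -g_new at k = 0, every
    ``restart_period`` iterations, when the previous gradient vanished, and
    whenever the combined direction is not a descent direction.
    """
    grad_new = np.asarray(grad_new, dtype=float)
    if (
        k == 0
        or grad_old is None
        or h_old is None
        or (restart_period > 0 and k % restart_period == 0)
    ):
        return -grad_new
    denom = float(np.dot(grad_old, grad_old))
    if denom == 0.0:
        return -grad_new
    beta = float(np.dot(grad_new, grad_new)) / denom
    h = -grad_new + beta * h_old
    if np.dot(h, grad_new) >= 0:  # not a descent direction: forced restart
        return -grad_new
    return h


def _closed_form_stepsize(N, h, plan: PlanObjectives, matrix) -> float:
    """Root of d chi^2 / d mu = 0 on the physical dose with frozen
    Heaviside sets, each gEUD term linearized along the direction.

    Every active term contributes c * (r - mu * s)^2 with residual r and
    slope s = directional dose (or gEUD) change per unit mu, so
    mu = sum(c r s) / sum(c s^2). Exact when all gEUD exponents are 1.
    """
    D = physical_dose(matrix, N)
    S = matrix.d @ np.asarray(h, dtype=float)
    return _closed_form_from_dose(D, S, plan)


def _closed_form_from_dose(D: np.ndarray, S: np.ndarray, plan: PlanObjectives) -> float:
    """Shared closed form given the current dose D and its linearized
    change S per unit mu along the search direction."""
    num = 0.0
    den = 0.0
    for voi, obj in plan.items:
        idx = voi.voxel_indices
        Dv, Sv = D[idx], S[idx]
        if isinstance(obj, TargetObjective):
            c = obj.w**2 / obj.delta**2
            r = obj.D_pre - Dv
            num += c * float(np.dot(r, Sv))
            den += c * float(np.dot(Sv, Sv))
        elif isinstance(obj, MaxDoseObjective):
            over = Dv > obj.D_max
            if over.any():
                c = obj.w**2 / obj.delta**2
                r = obj.D_max - Dv[over]
                num += c * float(np.dot(r, Sv[over]))
                den += c * float(np.dot(Sv[over], Sv[over]))
        elif isinstance(obj, GEUDObjective):
            g = compute_geud(Dv, obj.a)
            if g > obj.gEUD_0:
                gdot = float(np.dot(_geud_dose_coeff(Dv, obj.a, g), Sv))
                c = obj.w**2 / obj.delta**2
                num += c * (obj.gEUD_0 - g) * gdot
                den += c * gdot * gdot
        elif isinstance(obj, TargetGEUDObjective):
            g_min = compute_geud(Dv, obj.a_min)
            if g_min < obj.gEUD_0_min:
                gdot = float(np.dot(_geud_dose_coeff(Dv, obj.a_min, g_min), Sv))
                c = obj.w_min**2 / obj.delta_min**2
                num += c * (obj.gEUD_0_min - g_min) * gdot
                den += c * gdot * gdot
            g_max = compute_geud(Dv, obj.a_max)
            if g_max > obj.gEUD_0_max:
                gdot = float(np.dot(_geud_dose_coeff(Dv, obj.a_max, g_max), Sv))
                c = obj.w_max**2 / obj.delta_max**2
                num += c * (obj.gEUD_0_max - g_max) * gdot
                den += c * gdot * gdot
    if den == 0.0:
        return 0.0
    return max(num / den, 0.0)


def stepsize_physical(
    N,
    h,
    plan: PlanObjectives,
    matrix,
    mode: str = "analytic",
    grad: np.ndarray | None = None,
) -> float:
    """Stepsize along h for physical-dose optimization.

    ``analytic`` and ``linearized`` share the closed form (exact for pure
    voxel-dose / a = 1 plans; a linearization otherwise); ``backtracking``
    halves an upper bound until the Armijo condition holds.
    """
    h = np.asarray(h, dtype=float)
    if grad is not None and float(np.dot(h, grad)) > 0:
        raise NonDescentError("h is not a descent direction")
    if mode in ("analytic", "linearized"):
        return _closed_form_stepsize(N, h, plan, matrix)
    if mode != "backtracking":
        raise ValueError(f"unknown stepsize mode {mode!r}")
    phys_plan = replace(plan, dose_model="physical")
    engines = DoseEngines(matrix=matrix)
    mu = _closed_form_stepsize(N, h, plan, matrix)
    if mu == 0.0:
        return 0.0
    mu *= 2.0  # upper bound for the halving search
    c0 = total_cost(np.maximum(N, 0.0), phys_plan, engines)
    slope = float(np.dot(grad, h)) if grad is not None else 0.0
    for _ in range(50):
        trial = np.maximum(N + mu * h, 0.0)
        if total_cost(trial, phys_plan, engines) <= c0 + 1e-4 * mu * slope:
            return mu
        mu *= 0.5
    return 0.0


def stepsize_biological(
    N,
    h,
    plan: PlanObjectives,
    engines: DoseEngines,
    config: OptimizerConfig,
    grad: np.ndarray | None = None,
) -> tuple[float, int, bool]:
    """Damped stepsize for biological optimization, mu_bio = f * mu_lin.

    mu_lin is the closed-form root of the frozen-Heaviside quadratic with
    the dose response linearized around the current biological dose (slope
    = analytic RBE-weighted dose gradient along h); the damping factor f
    absorbs the neglected RBE curvature. If the biological cost still does
    not decrease at mu_bio, halve up to 20 times.
    Returns (mu, halvings, decreased)."""
    h = np.asarray(h, dtype=float)
    if grad is not None and float(np.dot(h, grad)) > 0:
        raise NonDescentError("h is not a descent direction")
    D = engines.dose(N, "biological")
    S = np.asarray(engines.dose_gradient_matrix(N, "biological") @ h).ravel()
    mu = config.f_damping * _closed_form_from_dose(D, S, plan)
    if mu == 0.0:
        return 0.0, 0, False
    c0 = total_cost(N, plan, engines)
    for halvings in range(_MAX_HALVINGS + 1):
        trial = np.maximum(N + mu * h, config.N_min)
        if total_cost(trial, plan, engines) < c0:
            return mu, halvings, True
        mu *= 0.5
    return mu, _MAX_HALVINGS, False


def optimize(
    plan: PlanObjectives,
    matrix,
    table=None,
    config: OptimizerConfig | None = None,
    N0: np.ndarray | None = None,
) -> OptimizerState:
    """Run the full line-search loop; all spots of all fields are
    optimized simultaneously (multiple-field optimization)."""
    if config is None:
        config = OptimizerConfig()
    engines = DoseEngines(matrix=matrix, table=table)
    N = preoptimize(matrix, plan, config.N_min) if N0 is None else np.asarray(N0, dtype=float)

    def _evaluate(N):
        """Dose, dose-gradient matrix, cost and cost gradient at N
        (one gradient-matrix build per accepted iterate)."""
        D = engines.dose(N, plan.dose_model)
        G = engines.dose_gradient_matrix(N, plan.dose_model)
        c = total_cost_from_dose(D, plan)
        g = np.asarray(G.T @ voxel_cost_coefficients(D, plan)).ravel()
        return D, G, c, g

    D, G, cost, grad = _evaluate(N)
    state = OptimizerState(k=0, N=N, cost=cost, grad=grad)

    h_old: np.ndarray | None = None
    grad_old: np.ndarray | None = None
    streak = 0
    rejects = 0

    for k in range(config.max_iter):
        gnorm = float(np.linalg.norm(grad))
        if gnorm == 0.0:
            state.converged = True
            break
        if config.algorithm == "sd":
            h = sd_direction(grad)
        else:
            h = cgfr_direction(grad, grad_old, h_old, k, config.restart_period)

        # propose a stepsize, then safeguard on the true model cost
        if plan.dose_model == "biological":
            S = np.asarray(G @ h).ravel()
            mu = config.f_damping * _closed_form_from_dose(D, S, plan)
        elif config.stepsize_mode == "backtracking":
            mu = stepsize_physical(N, h, plan, engines.matrix, mode="backtracking", grad=grad)
        else:
            mu = _closed_form_from_dose(D, np.asarray(G @ h).ravel(), plan)

        accepted = False
        halvings = 0
        if mu > 0:
            for halvings in range(_MAX_HALVINGS + 1):
                trial = np.maximum(N + mu * h, config.N_min)
                trial_cost = total_cost(trial, plan, engines)
                if trial_cost < cost:
                    accepted = True
                    break
                mu *= 0.5

        if accepted:
            rel_change = (cost - trial_cost) / cost if cost > 0 else 0.0
            N = trial
            grad_old = grad
            D, G, cost, grad = _evaluate(N)
            h_old = h
            rejects = 0
            streak = streak + 1 if rel_change < config.rel_tol else 0
        else:
            rejects += 1
            h_old = None  # force a CGFR restart after a failed step
            streak = 0

        state.history.append(
            IterationRecord(
                k=k, cost=cost, stepsize=mu, grad_norm=gnorm, accepted=accepted, halvings=halvings
            )
        )
        state.k = k + 1
        state.N, state.cost, state.grad = N, cost, grad

        if cost == 0.0 or streak >= _CONVERGED_STREAK:
            state.converged = True
            break
        if rejects >= _MAX_REJECTS:
            state.aborted = True
            break
    return state
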