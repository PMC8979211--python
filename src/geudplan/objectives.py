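"""Cost-function terms and their analytic gradients.

The total cost is a sum of quadratic penalties: a two-sided uniform-dose
term for the target, a one-sided (overdose-only) maximum-dose term per
OAR, a one-sided gEUD term per OAR, and optionally a two-term gEUD pair
for the target (a negative exponent controlling cold spots and a positive
exponent controlling hot spots). Every prescription carries a
normalization Delta = 0.025 times the prescribed value (half the assumed
percental accuracy of the dose calculation), so all terms are
dimensionless and comparable.

One-sided terms are gated by strict-inequality Heaviside factors: an OAR
voxel exactly at D_max, or an OAR exactly at its prescribed gEUD,
contributes nothing. Gradients freeze the Heaviside state of the current
iterate (active-set style); the line search handles crossings.

Gradients with respect to particle numbers accumulate a per-voxel
coefficient vector c and return ``G^T c`` where G is the dose-gradient
matrix (the influence matrix itself for physical dose, the analytic
low-dose RBE-weighted gradient for biological dose). For the gEUD terms
the voxel coefficient uses

    d gEUD / d D_i = gEUD^(1-a) D_i^(a-1) / M = (D_i / gEUD)^(a-1) / M

evaluated in log space so a = 20 stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dose import (
    DoseCorrelationMatrix,
    MixedFieldTable,
    biological_dose_from_particles,
    biological_dose_gradient,
    physical_dose,
)
from .metrics import compute_geud
from .phantom import VOIMask

__all__ = [
    "DELTA_FRACTION",
    "TargetObjective",
    "MaxDoseObjective",
    "GEUDObjective",
    "TargetGEUDObjective",
    "PlanObjectives",
    "DoseEngines",
    "voxel_dose_cost",
    "geud_cost",
    "target_geud_cost",
    "total_cost",
    "cost_gradient",
]

# Half of the assumed 5% dose-calculation accuracy; every quadratic term is
# normalized by (DELTA_FRACTION * prescription)^2.
DELTA_FRACTION = 0.025


@dataclass(frozen=True)
class TargetObjective:
    """Two-sided uniform-dose prescription for the target."""

    D_pre: float
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.D_pre <= 0:
            raise ValueError("D_pre must be positive")
        if self.w < 0:
            raise ValueError("weights must be nonnegative")

    @property
    def delta(self) -> float:
        return DELTA_FRACTION * self.D_pre


@dataclass(frozen=True)
class MaxDoseObjective:
    """One-sided maximum-dose penalty for an OAR (overdose only)."""

    D_max: float
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.D_max <= 0:
            raise ValueError("D_max must be positive")
        if self.w < 0:
            raise ValueError("weights must be nonnegative")

    @property
    def delta(self) -> float:
        return DELTA_FRACTION * self.D_max


@dataclass(frozen=True)
class GEUDObjective:
    """One-sided gEUD penalty for an OAR, active when gEUD > gEUD_0."""

    gEUD_0: float
    a: float
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.gEUD_0 <= 0:
            raise ValueError("gEUD_0 must be positive")
        if self.a < 1:
            raise ValueError("OAR gEUD objectives use a >= 1")
        if self.w < 0:
            raise ValueError("weights must be nonnegative")

    @property
    def delta(self) -> float:
        return DELTA_FRACTION * self.gEUD_0


@dataclass(frozen=True)
class TargetGEUDObjective:
    """Min/max gEUD pair replacing the uniform target prescription."""

    gEUD_0_min: float
    a_min: float
    gEUD_0_max: float
    a_max: float
    w_min: float = 1.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a_min < 0 < self.a_max):
            raise ValueError("need a_min < 0 < a_max")
        if self.gEUD_0_min > self.gEUD_0_max:
            raise ValueError("gEUD_0_min must not exceed gEUD_0_max")
        if self.gEUD_0_min <= 0:
            raise ValueError("prescriptions must be positive")

    @property
    def delta_min(self) -> float:
        return DELTA_FRACTION * self.gEUD_0_min

    @property
    def delta_max(self) -> float:
        return DELTA_FRACTION * self.gEUD_0_max


Objective = TargetObjective | MaxDoseObjective | GEUDObjective | TargetGEUDObjective


@dataclass(frozen=True)
class PlanObjectives:
    """Per-VOI objectives plus the dose model they are evaluated on."""

    items: tuple[tuple[VOIMask, Objective], ...]
    dose_model: str = "physical"  # "physical" | "biological"

    def __post_init__(self) -> None:
        if self.dose_model not in ("physical", "biological"):
            raise ValueError(f"unknown dose model {self.dose_model!r}")
        object.__setattr__(self, "items", tuple(self.items))
        target_objs = [
            o
            for v, o in self.items
            if isinstance(o, (TargetObjective, TargetGEUDObjective))
        ]
        if len(target_objs) != 1:
            raise ValueError("the plan needs exactly one target objective")
        for v, o in self.items:
            if isinstance(o, (TargetObjective, TargetGEUDObjective)) and v.role != "target":
                raise ValueError("target objectives must attach to the target VOI")
            if isinstance(o, (MaxDoseObjective, GEUDObjective)) and v.role != "oar":
                raise ValueError("OAR objectives must attach to an OAR VOI")

    @property
    def target_item(self) -> tuple[VOIMask, Objective]:
        return next(
            (v, o)
            for v, o in self.items
            if isinstance(o, (TargetObjective, TargetGEUDObjective))
        )


@dataclass(frozen=True)
class DoseEngines:
    """Bundle of the influence matrix and (optionally) the mixed-field
    radiosensitivity tables; evaluates dose and its gradient matrix for
    either dose model."""

    matrix: DoseCorrelationMatrix
    table: MixedFieldTable | None = None

    def dose(self, N, model: str) -> np.ndarray:
        if model == "physical":
            return physical_dose(self.matrix, N)
        if model == "biological":
            if self.table is None:
                raise ValueError("biological dose requires a radiosensitivity table")
            return biological_dose_from_particles(self.matrix, self.table, N)
        raise ValueError(f"unknown dose model {model!r}")

    def dose_gradient_matrix(self, N, model: str):
        if model == "physical":
            return self.matrix.d
        if model == "biological":
            if self.table is None:
                raise ValueError("biological dose requires a radiosensitivity table")
            return biological_dose_gradient(self.matrix, self.table, N)
        raise ValueError(f"unknown dose model {model!r}")


def _target_cost(D: np.ndarray, obj: TargetObjective) -> float:
    r = obj.D_pre - D
    return float(obj.w**2 * np.sum(r * r) / obj.delta**2)


def _maxdose_cost(D: np.ndarray, obj: MaxDoseObjective) -> float:
    over = D > obj.D_max  # strict: equality contributes nothing
    r = obj.D_max - D[over]
    return float(obj.w**2 * np.sum(r * r) / obj.delta**2)


def voxel_dose_cost(dose: np.ndarray, plan: PlanObjectives) -> float:
    """Uniform-target plus max-dose terms of the plan (gEUD terms excluded)."""
    dose = np.asarray(dose, dtype=float)
    cost = 0.0
    for voi, obj in plan.items:
        D = dose[voi.voxel_indices]
        if isinstance(obj, TargetObjective):
            cost += _target_cost(D, obj)
        elif isinstance(obj, MaxDoseObjective):
            cost += _maxdose_cost(D, obj)
    return cost


def geud_cost(dose: np.ndarray, mask: VOIMask, obj: GEUDObjective) -> float:
    """Quadratic penalty on gEUD excess over the prescription (one-sided)."""
    g = compute_geud(np.asarray(dose, dtype=float)[mask.voxel_indices], obj.a)
    if g <= obj.gEUD_0:
        return 0.0
    return float(obj.w**2 * (obj.gEUD_0 - g) ** 2 / obj.delta**2)


def target_geud_cost(dose: np.ndarray, mask: VOIMask, obj: TargetGEUDObjective) -> float:
    """Cold-spot (gEUD with a < 0 below prescription) plus hot-spot
    (gEUD with a > 0 above prescription) penalties for the target."""
    D = np.asarray(dose, dtype=float)[mask.voxel_indices]
    if (D == 0).any():
        raise ValueError("zero dose in the target: gEUD with a < 0 is undefined")
    cost = 0.0
    g_min = compute_geud(D, obj.a_min)
    if g_min < obj.gEUD_0_min:
        cost += obj.w_min**2 * (obj.gEUD_0_min - g_min) ** 2 / obj.delta_min**2
    g_max = compute_geud(D, obj.a_max)
    if g_max > obj.gEUD_0_max:
        cost += obj.w_max**2 * (obj.gEUD_0_max - g_max) ** 2 / obj.delta_max**2
    return float(cost)


def total_cost(N, plan: PlanObjectives, engines: DoseEngines) -> float:
    """Sum of all active terms on the plan's dose model."""
    dose = engines.dose(N, plan.dose_model)
    return total_cost_from_dose(dose, plan)


def total_cost_from_dose(dose: np.ndarray, plan: PlanObjectives) -> float:
    cost = voxel_dose_cost(dose, plan)
    for voi, obj in plan.items:
        if isinstance(obj, GEUDObjective):
            cost += geud_cost(dose, voi, obj)
        elif isinstance(obj, TargetGEUDObjective):
            cost += target_geud_cost(dose, voi, obj)
    return cost


def _geud_dose_coeff(D: np.ndarray, a: float, g: float) -> np.ndarray:
    """d gEUD / d D_i = (D_i / gEUD)^(a-1) / M, log-space, zeros by
    continuity (a > 1 -> 0; a = 1 -> 1/M for every voxel)."""
    M = D.size
    if a == 1:
        return np.full(M, 1.0 / M)
    out = np.zeros(M)
    pos = D > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.exp((a - 1.0) * (np.log(D[pos]) - np.log(g))) / M
    return out


def cost_gradient(N, plan: PlanObjectives, engines: DoseEngines) -> np.ndarray:
    """Gradient of the total cost with respect to the particle numbers."""
    dose = engines.dose(N, plan.dose_model)
    coeff = voxel_cost_coefficients(dose, plan)
    G = engines.dose_gradient_matrix(N, plan.dose_model)
    return np.asarray(G.T @ coeff).ravel()


def voxel_cost_coefficients(dose: np.ndarray, plan: PlanObjectives) -> np.ndarray:
    """Per-voxel dcost/dD_i, with Heaviside states frozen at this dose."""
    dose = np.asarray(dose, dtype=float)
    coeff = np.zeros(dose.size)
    for voi, obj in plan.items:
        idx = voi.voxel_indices
        D = dose[idx]
        if isinstance(obj, TargetObjective):
            coeff[idx] += -2.0 * obj.w**2 * (obj.D_pre - D) / obj.delta**2
        elif isinstance(obj, MaxDoseObjective):
            over = D > obj.D_max
            c = np.zeros_like(D)
            c[over] = -2.0 * obj.w**2 * (obj.D_max - D[over]) / obj.delta**2
            coeff[idx] += c
        elif isinstance(obj, GEUDObjective):
            g = compute_geud(D, obj.a)
            if g > obj.gEUD_0:
                pref = -2.0 * obj.w**2 * (obj.gEUD_0 - g) / obj.delta**2
                coeff[idx] += pref * _geud_dose_coeff(D, obj.a, g)
        elif isinstance(obj, TargetGEUDObjective):
            g_min = compute_geud(D, obj.a_min)
            if g_min < obj.gEUD_0_min:
                pref = -2.0 * obj.w_min**2 * (obj.gEUD_0_min - g_min) / obj.delta_min**2
                coeff[idx] += pref * _geud_dose_coeff(D, obj.a_min, g_min)
            g_max = compute_geud(D, obj.a_max)
            if g_max > obj.gEUD_0_max:
                pref = -2.0 * obj.w_max**2 * (obj.gEUD_0_max - g_max) / obj.delta_max**2
                coeff[idx] += pref * _geud_dose_coeff(D, obj.a_max, g_max)
    return coeff
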