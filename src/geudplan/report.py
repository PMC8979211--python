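"""Plan evaluation reports: per-VOI dosimetric indexes, DVHs, NTCP.

Mirrors the usual plan-comparison tables: per VOI the min/max/mean dose,
gEUD at the configured volume-effect exponent, conformity index for the
target, and — where an LKB model is attached — the NTCP of the full
course computed from the per-fraction mean dose (gEUD at a = 1) scaled by
the number of fractions, optionally EQD2-converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .metrics import (
    DVHCurve,
    FractionationScheme,
    NTCPModel,
    compute_dvh,
    compute_geud,
    conformity_index,
    lkb_ntcp_bounds,
    plan_ntcp,
)
from .objectives import (
    GEUDObjective,
    PlanObjectives,
    TargetGEUDObjective,
    TargetObjective,
)
from .phantom import PhantomScenario

__all__ = ["VOIReport", "PlanReport", "build_plan_report"]

# Default DVH bin width as a fraction of the prescription.
DVH_BIN_FRACTION = 0.005


@dataclass
class VOIReport:
    name: str
    role: str
    D_min: float
    D_max: float
    D_mean: float
    geud: float
    geud_a: float
    ci: float | None = None
    ntcp: float | None = None
    ntcp_low: float | None = None
    ntcp_high: float | None = None
    dvh: DVHCurve | None = None

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "role": self.role,
            "D_min": self.D_min,
            "D_max": self.D_max,
            "D_mean": self.D_mean,
            "geud": self.geud,
            "geud_a": self.geud_a,
        }
        if self.ci is not None:
            out["ci"] = self.ci
        if self.ntcp is not None:
            out["ntcp"] = self.ntcp
            out["ntcp_low"] = self.ntcp_low
            out["ntcp_high"] = self.ntcp_high
        return out


@dataclass
class PlanReport:
    vois: list[VOIReport]
    final_cost: float
    iterations: int
    converged: bool
    dose_model: str
    prescription: float

    def voi(self, name: str) -> VOIReport:
        for v in self.vois:
            if v.name == name:
                return v
        raise KeyError(f"no VOI named {name!r}")

    def to_dict(self) -> dict:
        return {
            "final_cost": self.final_cost,
            "iterations": self.iterations,
            "converged": self.converged,
            "dose_model": self.dose_model,
            "prescription": self.prescription,
            "vois": [v.to_dict() for v in self.vois],
        }


def _configured_a(plan: PlanObjectives, voi_name: str) -> float:
    for voi, obj in plan.items:
        if voi.name != voi_name:
            continue
        if isinstance(obj, GEUDObjective):
            return obj.a
        if isinstance(obj, TargetGEUDObjective):
            return obj.a_max
    return 1.0


def build_plan_report(
    dose: np.ndarray,
    phantom: PhantomScenario,
    plan: PlanObjectives,
    final_cost: float = float("nan"),
    iterations: int = 0,
    converged: bool = False,
    scheme: FractionationScheme | None = None,
    ntcp_models: Mapping[str, NTCPModel] | None = None,
    use_eqd2: bool = True,
    eqd2_convention: str = "prescribed_fraction",
) -> PlanReport:
    """Evaluate a dose vector against the phantom's VOIs.

    ``ntcp_models`` maps VOI names to LKB models; NTCP needs ``scheme``
    (the fractionation of the full course)."""
    dose = np.asarray(dose, dtype=float)
    _, tobj = plan.target_item
    if isinstance(tobj, TargetObjective):
        prescription = tobj.D_pre
    else:
        prescription = tobj.gEUD_0_max
    bin_width = DVH_BIN_FRACTION * prescription

    vois = []
    for voi in phantom.vois:
        D = dose[voi.voxel_indices]
        a = _configured_a(plan, voi.name)
        rep = VOIReport(
            name=voi.name,
            role=voi.role,
            D_min=float(D.min()),
            D_max=float(D.max()),
            D_mean=float(D.mean()),
            geud=compute_geud(D, a),
            geud_a=a,
            dvh=compute_dvh(D, bin_width),
        )
        if voi.role == "target":
            rep.ci = conformity_index(dose, voi.voxel_indices, prescription)
        if ntcp_models and voi.name in ntcp_models and scheme is not None:
            model = ntcp_models[voi.name]
            mean_per_frac = float(D.mean())
            rep.ntcp = plan_ntcp(
                mean_per_frac, scheme, model, use_eqd2=use_eqd2, convention=eqd2_convention
            )
            if model.TD50_ci is not None and model.m_ci is not None:
                total = mean_per_frac * scheme.n_frac
                if use_eqd2:
                    from .metrics import eqd2 as _eqd2

                    total = _eqd2(total, scheme, eqd2_convention)
                rep.ntcp_low, rep.ntcp_high = lkb_ntcp_bounds(total, model)
        vois.append(rep)
    return PlanReport(
        vois=vois,
        final_cost=float(final_cost),
        iterations=iterations,
        converged=converged,
        dose_model=plan.dose_model,
        prescription=prescription,
    )
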