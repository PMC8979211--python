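"""Plan configuration: a YAML/JSON schema validated with pydantic.

A plan config names a phantom scenario (or external matrix files), the
per-VOI objective blocks, the dose model, the optimizer settings, the
fractionation scheme and optional per-VOI LKB NTCP models. Unknown keys
are rejected so silent typos cannot change a plan.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import phantom as ph
from .metrics import DEFAULT_NTCP_MODEL, FractionationScheme, NTCPModel
from .objectives import (
    GEUDObjective,
    MaxDoseObjective,
    PlanObjectives,
    TargetGEUDObjective,
    TargetObjective,
)
from .optimizer import OptimizerConfig

__all__ = ["PlanConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomBlock(_Strict):
    scenario: Literal["wrapped_serial", "single_gland", "two_glands_multi_oar"]
    seed: int = 0


class RBEBlock(_Strict):
    alpha_x: float = ph.DEFAULT_ALPHA_X
    beta_x: float = ph.DEFAULT_BETA_X
    rbe_contrast: float = 3.0


class ObjectiveBlock(_Strict):
    voi: str
    type: Literal["uniform", "max_dose", "geud", "target_geud"]
    d_pre: Optional[float] = None
    d_max: Optional[float] = None
    geud0: Optional[float] = None
    a: Optional[float] = None
    geud0_min: Optional[float] = None
    a_min: Optional[float] = None
    geud0_max: Optional[float] = None
    a_max: Optional[float] = None
    weight: float = 1.0
    weight_min: Optional[float] = None
    weight_max: Optional[float] = None

    def build(self):
        if self.type == "uniform":
            if self.d_pre is None:
                raise ValueError(f"objective for {self.voi!r}: 'uniform' needs d_pre")
            return TargetObjective(D_pre=self.d_pre, w=self.weight)
        if self.type == "max_dose":
            if self.d_max is None:
                raise ValueError(f"objective for {self.voi!r}: 'max_dose' needs d_max")
            return MaxDoseObjective(D_max=self.d_max, w=self.weight)
        if self.type == "geud":
            if self.geud0 is None or self.a is None:
                raise ValueError(f"objective for {self.voi!r}: 'geud' needs geud0 and a")
            return GEUDObjective(gEUD_0=self.geud0, a=self.a, w=self.weight)
        if None in (self.geud0_min, self.a_min, self.geud0_max, self.a_max):
            raise ValueError(
                f"objective for {self.voi!r}: 'target_geud' needs geud0_min/a_min/geud0_max/a_max"
            )
        return TargetGEUDObjective(
            gEUD_0_min=self.geud0_min,
            a_min=self.a_min,
            gEUD_0_max=self.geud0_max,
            a_max=self.a_max,
            w_min=self.weight_min if self.weight_min is not None else self.weight,
            w_max=self.weight_max if self.weight_max is not None else self.weight,
        )


class OptimizerBlock(_Strict):
    algorithm: Literal["sd", "cgfr"] = "cgfr"
    max_iter: int = 500
    rel_tol: float = 1e-5
    f_damping: float = 0.5
    n_min: float = 0.0
    restart_period: int = 25
    stepsize_mode: Literal["analytic", "linearized", "backtracking"] = "linearized"

    def build(self) -> OptimizerConfig:
        return OptimizerConfig(
            algorithm=self.algorithm,
            max_iter=self.max_iter,
            rel_tol=self.rel_tol,
            f_damping=self.f_damping,
            N_min=self.n_min,
            restart_period=self.restart_period,
            stepsize_mode=self.stepsize_mode,
        )


class FractionationBlock(_Strict):
    n_fractions: int = 20
    prescription_per_fraction: float = 3.0
    alpha_beta: float = 2.0
    eqd2_convention: Literal["prescribed_fraction", "literal"] = "prescribed_fraction"
    use_eqd2: bool = True

    def build(self) -> FractionationScheme:
        return FractionationScheme(
            n_frac=self.n_fractions,
            d_ref=self.prescription_per_fraction,
            alpha_beta=self.alpha_beta,
        )


class NTCPBlock(_Strict):
    td50: float = DEFAULT_NTCP_MODEL.TD50
    m: float = DEFAULT_NTCP_MODEL.m

    def build(self) -> NTCPModel:
        if (self.td50, self.m) == (DEFAULT_NTCP_MODEL.TD50, DEFAULT_NTCP_MODEL.m):
            return DEFAULT_NTCP_MODEL
        return NTCPModel(TD50=self.td50, m=self.m)


class PlanConfig(_Strict):
    phantom: PhantomBlock
    dose_model: Literal["physical", "biological"] = "biological"
    rbe: RBEBlock = Field(default_factory=RBEBlock)
    objectives: list[ObjectiveBlock]
    optimizer: OptimizerBlock = Field(default_factory=OptimizerBlock)
    fractionation: FractionationBlock = Field(default_factory=FractionationBlock)
    ntcp: dict[str, NTCPBlock] = Field(default_factory=dict)
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _at_least_one_objective(self):
        if not self.objectives:
            raise ValueError("the plan needs at least one objective")
        return self

    def build_phantom(self) -> ph.PhantomScenario:
        return ph.build_phantom(self.phantom.scenario, self.phantom.seed)

    def build_objectives(self, phantom: ph.PhantomScenario) -> PlanObjectives:
        items = []
        for block in self.objectives:
            voi = phantom.voi(block.voi)  # KeyError with the name if absent
            items.append((voi, block.build()))
        return PlanObjectives(items=tuple(items), dose_model=self.dose_model)

    def build_ntcp_models(self) -> dict[str, NTCPModel]:
        return {name: block.build() for name, block in self.ntcp.items()}


def load_config(path: str | Path) -> PlanConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PlanConfig.model_validate(raw)
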