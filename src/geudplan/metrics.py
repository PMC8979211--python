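"""Plan-evaluation quantities: gEUD, DVH, LKB NTCP, EQD2, conformity.

The generalized equivalent uniform dose (gEUD) is the power mean

    gEUD = ( (1/M) sum_i D_i^a )^(1/a)

whose volume-effect exponent ``a`` interpolates between the mean dose
(a = 1, parallel organs), the maximum dose (a >> 1, serial organs) and the
minimum dose (a -> -inf, used for target cold spots). NTCP uses the
Lyman-Kutcher-Burman probit in gEUD; EQD2 rescales a total dose to the
equivalent delivered in 2-Gy fractions via the linear-quadratic
fractionation factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, ndtr

__all__ = [
    "GEUDParams",
    "NTCPModel",
    "FractionationScheme",
    "DVHCurve",
    "compute_geud",
    "compute_dvh",
    "lkb_ntcp",
    "eqd2",
    "plan_ntcp",
    "conformity_index",
    "DEFAULT_NTCP_MODEL",
]


@dataclass(frozen=True)
class GEUDParams:
    """Volume-effect parameter of the gEUD power mean (a != 0)."""

    a: float

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("the gEUD power mean is undefined at a = 0")


@dataclass(frozen=True)
class NTCPModel:
    """LKB dose-response: TD50 (Gy, total dose at 50% complication
    probability) and slope m; optional 95% CI corners for error bars."""

    TD50: float
    m: float
    TD50_ci: tuple[float, float] | None = None
    m_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.TD50 <= 0 or self.m <= 0:
            raise ValueError("TD50 and m must be positive")


# Parotid-gland LKB fit (mean-dose organ, a = 1): TD50 = 39.9 Gy
# (95% CI 37.3-42.8), m = 0.40 (0.34-0.51).
DEFAULT_NTCP_MODEL = NTCPModel(TD50=39.9, m=0.40, TD50_ci=(37.3, 42.8), m_ci=(0.34, 0.51))


@dataclass(frozen=True)
class FractionationScheme:
    """n_frac fractions; d_ref is the fraction dose used by the
    prescribed-fraction EQD2 convention; alpha_beta in Gy."""

    n_frac: int
    d_ref: float
    alpha_beta: float

    def __post_init__(self) -> None:
        if self.n_frac < 1:
            raise ValueError("n_frac must be >= 1")
        if self.alpha_beta <= 0:
            raise ValueError("alpha/beta must be positive")


def compute_geud(doses, a: float | GEUDParams) -> float:
    """Power-law mean of the voxel doses of one VOI.

    Evaluated in log space with max-factoring so large |a| (e.g. 20) does
    not overflow. Zero doses are allowed for a > 0 (they contribute zero);
    for a < 0 any zero dose is an error (the power mean diverges).
    """
    if isinstance(a, GEUDParams):
        a = a.a
    if a == 0:
        raise ValueError("the gEUD power mean is undefined at a = 0")
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("empty dose vector")
    if (doses < 0).any():
        raise ValueError("doses must be nonnegative")
    if a < 0 and (doses == 0).any():
        raise ValueError("zero dose with a < 0 makes the gEUD power mean undefined")
    if (doses == 0).all():
        return 0.0
    with np.errstate(divide="ignore"):
        logd = np.log(doses)
    # log gEUD = ( logsumexp(a log D) - log M ) / a
    return float(np.exp((logsumexp(a * logd) - np.log(doses.size)) / a))


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: percent of VOI volume receiving at
    least each edge dose."""

    dose_edges: np.ndarray  # Gy, increasing from 0
    volume_percent: np.ndarray  # %, non-increasing from 100

    def volume_at(self, dose: float) -> float:
        """Volume percent at-or-above ``dose`` (step lookup)."""
        idx = int(np.searchsorted(self.dose_edges, dose, side="right")) - 1
        if idx < 0:
            return 100.0
        return float(self.volume_percent[idx])


def compute_dvh(doses, bin_width: float) -> DVHCurve:
    """Cumulative volume-at-or-above-dose curve, V(0) = 100%."""
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("empty VOI")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(doses.max() / bin_width)) + 2 if doses.max() > 0 else 2
    edges = np.arange(n_bins) * bin_width
    volume = np.array([(doses >= e).mean() * 100.0 for e in edges])
    return DVHCurve(dose_edges=edges, volume_percent=volume)


def lkb_ntcp(geud_total: float, model: NTCPModel = DEFAULT_NTCP_MODEL) -> float:
    """LKB complication probability Phi((gEUD - TD50) / (m TD50))."""
    if geud_total < 0:
        raise ValueError("gEUD must be nonnegative")
    u = (geud_total - model.TD50) / (model.m * model.TD50)
    return float(ndtr(u))


def lkb_ntcp_bounds(geud_total: float, model: NTCPModel) -> tuple[float, float]:
    """(low, high) NTCP over the CI corners of (TD50, m); the steepest,
    lowest-TD50 corner gives the high value below TD50 and vice versa."""
    if model.TD50_ci is None or model.m_ci is None:
        raise ValueError("model carries no confidence intervals")
    corners = [
        lkb_ntcp(geud_total, NTCPModel(t, mm))
        for t in model.TD50_ci
        for mm in model.m_ci
    ]
    return min(corners), max(corners)


def eqd2(
    total: float, scheme: FractionationScheme, convention: str = "prescribed_fraction"
) -> float:
    """Equivalent total dose in 2-Gy fractions.

    ``literal`` uses the structure's own per-fraction dose total/n_frac in
    the fractionation factor; ``prescribed_fraction`` (default) uses the
    plan's prescribed fraction dose ``d_ref``. Both return
    ``total * (alpha/beta + d) / (alpha/beta + 2)``.
    """
    if total < 0:
        raise ValueError("total dose must be nonnegative")
    if convention == "literal":
        d = total / scheme.n_frac
    elif convention == "prescribed_fraction":
        d = scheme.d_ref
    else:
        raise ValueError(f"unknown EQD2 convention {convention!r}")
    return total * (scheme.alpha_beta + d) / (scheme.alpha_beta + 2.0)


def plan_ntcp(
    mean_dose_per_fraction: float,
    scheme: FractionationScheme,
    model: NTCPModel = DEFAULT_NTCP_MODEL,
    use_eqd2: bool = True,
    convention: str = "prescribed_fraction",
) -> float:
    """NTCP of a full course: per-fraction (g)EUD times n_frac, optionally
    EQD2-converted, pushed through the LKB model."""
    total = mean_dose_per_fraction * scheme.n_frac
    if use_eqd2:
        total = eqd2(total, scheme, convention)
    return lkb_ntcp(total, model)


def conformity_index(dose, target_indices, prescription: float) -> float:
    """Volume of the 95% isodose (whole grid) over the target volume."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    dose = np.asarray(dose, dtype=float).ravel()
    target_indices = np.asarray(target_indices)
    n_iso = int((dose >= 0.95 * prescription).sum())
    return n_iso / target_indices.size
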