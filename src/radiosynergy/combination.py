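"""Fixed-ratio combination-index analysis and isobologram coordinates.

The design follows the classical fixed-ratio (constant-ratio) protocol: two
agents titrated alone and in mixtures that blend fraction w_A of agent A's
titration with fraction w_B = 1 - w_A of agent B's. The mixture dose axis is
the dimensionless fraction f of the top concentrations, so a mixture well at
fraction f contains d_A = w_A·f·top_A and d_B = w_B·f·top_B in native units.

For each ratio the combined dose reaching the target effect (50% by
default) is read off a 4PL fit of the mixture curve by closed-form
inversion (the mixture's absolute iso-effect dose; a global median-effect
linearization would bias the crossing on curved combination surfaces). It
is decomposed into component doses and scored with the two-term combination
index

    CI = d_A / D_A + d_B / D_B,

where D_A, D_B are the single-agent doses producing the same effect under
their median-effect fits. CI < 0.8 is called synergistic, CI > 1.2
antagonistic, and the closed interval [0.8, 1.2] additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dose_response import (
    DoseResponseCurve,
    FourPLFit,
    MedianEffectFit,
    dose_at_effect,
    fit_4pl,
    fit_median_effect,
    inverse_4pl,
)

__all__ = [
    "NINE_RATIO_WEIGHTS",
    "FixedRatioDesign",
    "RatioCI",
    "CombinationIndexResult",
    "IsobologramPoint",
    "classify_ci",
    "combination_index",
    "isobologram_points",
]

#: The nine fixed-ratio weight pairs 0.9:0.1 ... 0.1:0.9.
NINE_RATIO_WEIGHTS: tuple[tuple[float, float], ...] = tuple(
    (round(0.1 * k, 1), round(1.0 - 0.1 * k, 1)) for k in range(9, 0, -1)
)

CI_SYNERGY_THRESHOLD = 0.8
CI_ANTAGONISM_THRESHOLD = 1.2


def classify_ci(ci: float) -> str:
    """Map a combination index to synergistic / additive / antagonistic.

    Boundary values 0.8 and 1.2 are classified additive, so the three classes
    partition the CI line with no gaps or overlaps.
    """
    if ci < CI_SYNERGY_THRESHOLD:
        return "synergistic"
    if ci > CI_ANTAGONISM_THRESHOLD:
        return "antagonistic"
    return "additive"


@dataclass(frozen=True)
class FixedRatioDesign:
    """Top concentrations of the two titrations and the ratio weights."""

    top_conc_a: float
    top_conc_b: float
    unit_a: str = ""
    unit_b: str = ""
    weights: tuple[tuple[float, float], ...] = NINE_RATIO_WEIGHTS

    def __post_init__(self) -> None:
        if self.top_conc_a <= 0 or self.top_conc_b <= 0:
            raise ValueError("top concentrations must be positive")
        for wa, wb in self.weights:
            if not (0.0 < wa < 1.0 and 0.0 < wb < 1.0):
                raise ValueError(f"weights must lie strictly inside (0,1): ({wa}, {wb})")
            if abs(wa + wb - 1.0) > 1e-9:
                raise ValueError(f"weights must sum to 1: ({wa}, {wb})")


@dataclass
class RatioCI:
    weight_a: float
    weight_b: float
    ci: float | None
    dose_a: float | None
    dose_b: float | None
    mixture_fit: MedianEffectFit | None
    excluded: bool = False
    reason: str = ""


@dataclass
class CombinationIndexResult:
    per_ratio: list[RatioCI]
    average_ci: float
    classification: str
    effect_level: float
    n_excluded: int


def combination_index(
    design: FixedRatioDesign,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    mixture_curves: list[DoseResponseCurve],
    effect_level: float = 0.5,
    clip: tuple[float, float] = (1e-3, 1.0 - 1e-3),
) -> CombinationIndexResult:
    """Per-ratio and average combination index at the given effect level.

    ``mixture_curves`` must hold one curve per design weight pair, with
    concentrations on the fraction-of-top axis. A mixture whose fitted curve
    never reaches the target effect level (or whose fit fails) is flagged,
    excluded from the average, and counted in ``n_excluded``.
    """
    if len(mixture_curves) != len(design.weights):
        raise ValueError(
            f"expected {len(design.weights)} mixture curves, got {len(mixture_curves)}"
        )
    d_a50 = dose_at_effect(fit_a, effect_level)
    d_b50 = dose_at_effect(fit_b, effect_level)
    per_ratio: list[RatioCI] = []
    for (wa, wb), curve in zip(design.weights, mixture_curves):
        entry = RatioCI(wa, wb, None, None, None, None)
        try:
            mix4pl = fit_4pl(curve)
            f_eff, status = inverse_4pl(mix4pl, 1.0 - effect_level)
        except (ValueError, RuntimeError) as exc:
            entry.excluded = True
            entry.reason = str(exc)
            per_ratio.append(entry)
            continue
        if f_eff is None:
            entry.excluded = True
            entry.reason = f"mixture never reaches {effect_level:.0%} effect ({status.value})"
            per_ratio.append(entry)
            continue
        try:
            entry.mixture_fit = fit_median_effect(curve, clip=clip)
        except ValueError:
            entry.mixture_fit = None  # reported fit only; CI uses the 4PL crossing
        entry.dose_a = wa * f_eff * design.top_conc_a
        entry.dose_b = wb * f_eff * design.top_conc_b
        entry.ci = entry.dose_a / d_a50 + entry.dose_b / d_b50
        per_ratio.append(entry)
    evaluable = [r.ci for r in per_ratio if not r.excluded]
    n_excluded = sum(r.excluded for r in per_ratio)
    if not evaluable:
        raise ValueError("no evaluable ratio: every mixture failed to reach the effect level")
    if n_excluded:
        warnings.warn(
            f"{n_excluded} of {len(per_ratio)} ratios excluded from the average CI",
            stacklevel=2,
        )
    avg_ci = float(np.mean(evaluable))
    return CombinationIndexResult(
        per_ratio, avg_ci, classify_ci(avg_ci), effect_level, n_excluded
    )


@dataclass(frozen=True)
class IsobologramPoint:
    dose_a: float
    dose_b: float
    effect_level: float = 0.5


def isobologram_points(
    fit_a: FourPLFit,
    fit_b: FourPLFit,
    ci_result: CombinationIndexResult,
) -> list[IsobologramPoint]:
    """Axis intercepts at the single-agent absolute IC50s plus one point per
    evaluable ratio. Points below the straight line between the intercepts
    correspond to CI < 1 (when the median-effect and 4PL IC50s agree)."""
    if fit_a.absolute_ic50 is None or fit_b.absolute_ic50 is None:
        bad = fit_a if fit_a.absolute_ic50 is None else fit_b
        raise ValueError(
            f"absolute IC50 undefined for {bad.agent_label!r} ({bad.ic50_status.value})"
        )
    eff = ci_result.effect_level
    pts = [
        IsobologramPoint(fit_a.absolute_ic50, 0.0, eff),
        IsobologramPoint(0.0, fit_b.absolute_ic50, eff),
    ]
    for r in ci_result.per_ratio:
        if not r.excluded:
            pts.append(IsobologramPoint(r.dose_a, r.dose_b, eff))
    return pts
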