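"""Viability normalization, 4PL fitting, absolute IC50 and median-effect fits.

The four-parameter logistic (4PL) is fitted in log10-dose space,

    v(D) = bottom + (top - bottom) / (1 + (D / ec50)^hill),

with viability as fraction of untreated control. A positive hill slope means
viability falls with dose. The absolute IC50 is the dose at which predicted
viability equals 0.5 of control (not 0.5 of the fitted span); it inverts the
4PL in closed form.

The median-effect model fa/fu = (D/Dm)^m is fitted by linear regression of
log10(fa/fu) on log10 D, with fa = 1 - viability defined against untreated
control.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseCurve",
    "FourPLFit",
    "Ic50Status",
    "MedianEffectFit",
    "normalize_viability",
    "fit_4pl",
    "absolute_ic50",
    "fit_median_effect",
    "dose_at_effect",
]


class Ic50Status(str, enum.Enum):
    OK = "ok"
    BOTTOM_ABOVE_HALF = "bottom-above-half"
    TOP_BELOW_HALF = "top-below-half"
    FLAT = "flat-curve"


@dataclass
class DoseResponseCurve:
    """Concentration/viability series for one agent or one fixed-ratio mixture.

    ``concentrations`` are in the native unit of the agent (``unit``); for
    mixtures the internal axis is the dimensionless fraction of the top
    concentrations (``unit="fraction"``). ``viability`` is fraction of
    untreated control.
    """

    agent_label: str
    concentrations: np.ndarray
    viability: np.ndarray
    unit: str = ""
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise ValueError("concentrations and viability must have equal length")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability values must be finite")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def averaged(self) -> "DoseResponseCurve":
        """Replicates averaged per distinct concentration (sorted ascending)."""
        conc, inv = np.unique(self.concentrations, return_inverse=True)
        v = np.bincount(inv, weights=self.viability) / np.bincount(inv)
        return DoseResponseCurve(self.agent_label, conc, v, self.unit)

    @property
    def n_distinct(self) -> int:
        return np.unique(self.concentrations[self.concentrations > 0]).size


@dataclass
class FourPLFit:
    top: float
    bottom: float
    hill: float
    ec50: float
    absolute_ic50: float | None
    ic50_status: Ic50Status
    residual_sse: float
    agent_label: str = ""

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(d > 0, d / self.ec50, 0.0)
            val = self.bottom + (self.top - self.bottom) / (1.0 + ratio**self.hill)
        # dose 0 is the control limit: top for hill>0, bottom for hill<0
        zero_val = self.top if self.hill >= 0 else self.bottom
        val = np.where(d == 0, zero_val, val)
        return float(val) if np.isscalar(dose) else val


@dataclass
class MedianEffectFit:
    dm: float
    m: float
    r_squared: float
    n_points: int
    agent_label: str = ""


def normalize_viability(raw_signals, control_signals, blank_signals) -> np.ndarray:
    """Background-subtracted fraction-of-control viability.

    Returns (raw - mean(blank)) / (mean(control) - mean(blank)); wells equal
    to the control mean map to exactly 1.0.
    """
    raw = np.asarray(raw_signals, dtype=float)
    control = float(np.mean(control_signals))
    blank = float(np.mean(blank_signals))
    if control <= blank:
        raise ValueError(
            f"degenerate plate: control mean {control:g} <= blank mean {blank:g}"
        )
    return (raw - blank) / (control - blank)


def _4pl(logd: np.ndarray, top: float, bottom: float, log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ec50)))


def fit_4pl(curve: DoseResponseCurve) -> FourPLFit:
    """Least-squares 4PL fit in log10-dose space with multi-start initialization.

    Three deterministic starts (data-driven, steep, shallow) guard against
    local minima; the best residual sum of squares wins. Wells at dose zero
    are excluded from the log-dose fit (they are controls by construction).
    """
    mask = curve.concentrations > 0
    d = curve.concentrations[mask]
    v = curve.viability[mask]
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct positive concentrations")
    span = float(np.ptp(v))
    if span < 1e-9:
        mean_v = float(np.mean(v))
        status = Ic50Status.FLAT if abs(mean_v - 0.5) < 1e-9 else (
            Ic50Status.BOTTOM_ABOVE_HALF if mean_v > 0.5 else Ic50Status.TOP_BELOW_HALF
        )
        return FourPLFit(mean_v, mean_v, 0.0, float(np.sqrt(d.min() * d.max())),
                         None, status, 0.0, curve.agent_label)

    logd = np.log10(d)
    top0, bot0 = float(v.max()), float(v.min())
    # log-dose where the response crosses mid-span, by linear interpolation
    order = np.argsort(logd)
    mid = 0.5 * (top0 + bot0)
    lx, lv = logd[order], v[order]
    crossing = lx[np.argmin(np.abs(lv - mid))]
    sign = -1.0 if stats.linregress(logd, v).slope > 0 else 1.0
    starts = [
        (top0, bot0, crossing, sign * 1.0),
        (top0, bot0, crossing, sign * 3.0),
        (top0, bot0, crossing, sign * 0.5),
    ]
    lo = [-0.5, -0.5, logd.min() - 3.0, -10.0]
    hi = [2.0, 2.0, logd.max() + 3.0, 10.0]
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: _4pl(logd, *p) - v, p0, bounds=(lo, hi), method="trf"
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"4PL fit failed to converge for {curve.agent_label!r} "
            f"(n={d.size}, span={span:.3g})"
        )
    top, bottom, log_ec50, hill = best.x
    sse = float(2 * best.cost)
    fit = FourPLFit(float(top), float(bottom), float(hill), float(10.0**log_ec50),
                    None, Ic50Status.OK, sse, curve.agent_label)
    ic50, status = _invert_at_half(fit)
    fit.absolute_ic50 = ic50
    fit.ic50_status = status
    return fit


def _invert_at_half(fit: FourPLFit) -> tuple[float | None, Ic50Status]:
    top, bottom, hill, ec50 = fit.top, fit.bottom, fit.hill, fit.ec50
    if abs(hill) < 1e-12 or abs(top - bottom) < 1e-12:
        mean_v = 0.5 * (top + bottom)
        if mean_v > 0.5:
            return None, Ic50Status.BOTTOM_ABOVE_HALF
        if mean_v < 0.5:
            return None, Ic50Status.TOP_BELOW_HALF
        return None, Ic50Status.FLAT
    if min(top, bottom) >= 0.5:
        return None, Ic50Status.BOTTOM_ABOVE_HALF
    if max(top, bottom) <= 0.5:
        return None, Ic50Status.TOP_BELOW_HALF
    # 0.5 = bottom + (top-bottom)/(1+r)  =>  r = (top-0.5)/(0.5-bottom)
    r = (top - 0.5) / (0.5 - bottom)
    return float(ec50 * r ** (1.0 / hill)), Ic50Status.OK


def absolute_ic50(fit: FourPLFit) -> tuple[float | None, Ic50Status]:
    """Dose at which the fitted curve predicts viability = 0.5 of control.

    Closed-form inversion of the 4PL. Undefined (with an explicit status
    distinguishing the two failure modes) when the curve never crosses 0.5.
    """
    return _invert_at_half(fit)


def inverse_4pl(fit: FourPLFit, viability: float) -> tuple[float | None, Ic50Status]:
    """Dose at which the fitted 4PL predicts the given fraction-of-control
    viability; same closed form and statuses as :func:`absolute_ic50`."""
    shifted = FourPLFit(
        fit.top - viability + 0.5, fit.bottom - viability + 0.5, fit.hill,
        fit.ec50, None, Ic50Status.OK, fit.residual_sse, fit.agent_label,
    )
    return _invert_at_half(shifted)


def fit_median_effect(
    curve: DoseResponseCurve,
    clip: tuple[float, float] = (1e-3, 1.0 - 1e-3),
) -> MedianEffectFit:
    """Fit fa/fu = (D/Dm)^m by linear regression of log(fa/fu) on log D.

    Replicates are averaged per concentration first. fa = 1 - viability
    (against untreated control); viabilities are clipped into ``clip`` before
    the log transform, and wells that sit at a clip boundary (saturated at
    either end of the assay's dynamic range) are excluded from the
    regression — they carry no slope information. At least 3 points strictly
    inside the clip interval are required. slope = m, intercept =
    -m·log10(Dm).
    """
    avg = curve.averaged()
    mask = avg.concentrations > 0
    d = avg.concentrations[mask]
    v = np.clip(avg.viability[mask], clip[0], clip[1])
    usable = (v > clip[0]) & (v < clip[1])
    if usable.sum() < 3:
        raise ValueError(
            f"insufficient dynamic range for {curve.agent_label!r}: "
            f"only {int(usable.sum())} points with fa strictly inside (0, 1)"
        )
    d, v = d[usable], v[usable]
    fa = 1.0 - v
    x = np.log10(d)
    y = np.log10(fa / (1.0 - fa))
    reg = stats.linregress(x, y)
    m = float(reg.slope)
    dm = float(10.0 ** (-reg.intercept / m)) if m != 0 else float("nan")
    return MedianEffectFit(dm, m, float(reg.rvalue**2), int(d.size), curve.agent_label)


def dose_at_effect(fit: MedianEffectFit, fa: float = 0.5) -> float:
    """Dose producing fraction-affected ``fa`` under the median-effect model.

    D = Dm · (fa/fu)^(1/m); at fa = 0.5 this is Dm itself.
    """
    if not 0.0 < fa < 1.0:
        raise ValueError("effect level must be strictly inside (0, 1)")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)
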