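"""Xenograft efficacy metrics: doubling time, T/C ratios, ANOVA/Tukey,
and Bliss-additivity synergy calls.

T/C is the treated-group mean tumor volume divided by the vehicle-group mean
at a reference day (lower = more efficacious). Synergy of a combination arm
is judged against the Bliss-independence null. Two conventions are offered:

* ``inhibition-scale`` (default): expected combination T/C = A·B. This is
  the Bliss product applied to survival-like quantities and is algebraically
  identical to applying C = A + B − A·B on the inhibition scale 1 − T/C.
* ``tc-literal``: C = A + B − A·B applied to the T/C values themselves.

A combination is called synergistic when the observed T/C undershoots the
expected value by more than the margin (0.10 absolute T/C units by default),
antagonistic when it overshoots by more than the margin, additive otherwise
(boundaries inclusive).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "EfficacyStudy",
    "TCResult",
    "BlissCall",
    "HUMANE_ENDPOINT_MM3",
    "doubling_time",
    "group_doubling_time",
    "tc_ratio",
    "anova_tukey",
    "bliss_expected",
    "bliss_call",
    "bliss_table",
]

HUMANE_ENDPOINT_MM3 = 1500.0

INHIBITION_SCALE = "inhibition-scale"
TC_LITERAL = "tc-literal"


@dataclass
class EfficacyStudy:
    """Per-animal tumor-volume time series grouped by treatment arm.

    ``measurements`` columns: animal_id, group, day, volume_mm3,
    body_weight_g. ``arm_doses`` optionally maps group label to
    (ttc_kbq_per_kg, olaparib_mg_per_kg) for Bliss bookkeeping. Animals are
    censored at the humane endpoint: measurements after the first day with
    volume >= 1,500 mm³ are excluded from group means (the triggering
    measurement itself is kept; no carry-forward).
    """

    measurements: pd.DataFrame
    vehicle_group: str = "vehicle"
    arm_doses: dict[str, tuple[float, float]] = field(default_factory=dict)
    endpoint_mm3: float = HUMANE_ENDPOINT_MM3

    def __post_init__(self) -> None:
        df = self.measurements
        required = {"animal_id", "group", "day", "volume_mm3"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"measurements missing columns {sorted(missing)}")
        if (df["volume_mm3"] < 0).any():
            raise ValueError("tumor volumes must be non-negative")
        groups_per_animal = df.groupby("animal_id")["group"].nunique()
        if (groups_per_animal > 1).any():
            raise ValueError("each animal must belong to exactly one group")

    def censor_days(self) -> dict[object, float]:
        """First day each animal hits the endpoint (absent = never censored)."""
        hit = self.measurements[self.measurements["volume_mm3"] >= self.endpoint_mm3]
        return hit.groupby("animal_id")["day"].min().to_dict()

    def uncensored_at(self, day: float) -> pd.DataFrame:
        """Measurements at ``day`` from animals not yet past their censoring day."""
        cens = self.censor_days()
        at = self.measurements[self.measurements["day"] == day]
        keep = [cens.get(a, np.inf) >= day for a in at["animal_id"]]
        return at[np.asarray(keep, bool)]

    def groups(self) -> list[str]:
        return sorted(self.measurements["group"].unique())

    def default_reference_day(self) -> float:
        """Last study day on which every vehicle animal remains uncensored."""
        veh = self.measurements[self.measurements["group"] == self.vehicle_group]
        if veh.empty:
            raise ValueError(f"no vehicle group {self.vehicle_group!r} in study")
        cens = self.censor_days()
        n_vehicle = veh["animal_id"].nunique()
        ok_days = [
            d
            for d, sub in veh.groupby("day")
            if sub["animal_id"].nunique() == n_vehicle
            and all(cens.get(a, np.inf) >= d for a in sub["animal_id"])
        ]
        if not ok_days:
            raise ValueError("no day with all vehicle animals uncensored")
        return max(ok_days)


@dataclass
class TCResult:
    group: str
    reference_day: float
    t_over_c: float
    p_value: float | None
    significant: bool | None
    n_treated: int
    n_vehicle: int


@dataclass
class BlissCall:
    a_tc: float
    b_tc: float
    expected_tc: float
    observed_tc: float
    margin: float
    call: str
    convention: str


def doubling_time(days, volumes) -> tuple[float | None, str]:
    """Tumor volume doubling time from log-linear regression of one animal.

    Returns (ln 2 / slope, "ok"), or (None, "no growth") when the fitted
    slope is non-positive. Requires >=3 time points with positive volume.
    """
    days = np.asarray(days, float)
    volumes = np.asarray(volumes, float)
    mask = volumes > 0
    if mask.sum() < 3:
        raise ValueError("need at least 3 time points with positive volume")
    slope = stats.linregress(days[mask], np.log(volumes[mask])).slope
    if slope <= 0:
        return None, "no growth"
    return float(np.log(2.0) / slope), "ok"


def group_doubling_time(study: EfficacyStudy, group: str) -> tuple[float | None, int]:
    """Mean doubling time over a group's animals (growing animals only).

    Returns (mean days, number of animals contributing); censored
    measurements are excluded before the per-animal regressions.
    """
    cens = study.censor_days()
    sub = study.measurements[study.measurements["group"] == group]
    if sub.empty:
        raise ValueError(f"unknown group {group!r}")
    tds = []
    for animal, rows in sub.groupby("animal_id"):
        rows = rows[rows["day"] <= cens.get(animal, np.inf)]
        if (rows["volume_mm3"] > 0).sum() < 3:
            continue
        td, status = doubling_time(rows["day"], rows["volume_mm3"])
        if status == "ok":
            tds.append(td)
    if not tds:
        return None, 0
    return float(np.mean(tds)), len(tds)


def tc_ratio(
    study: EfficacyStudy,
    group: str,
    reference_day: float | None = None,
    with_significance: bool = True,
) -> TCResult:
    """Treatment-over-control ratio of mean tumor volumes at the reference day.

    Attaches the Tukey-adjusted p-value of the group-vs-vehicle contrast from
    the one-way ANOVA across all arms at that day.
    """
    day = study.default_reference_day() if reference_day is None else reference_day
    at = study.uncensored_at(day)
    veh = at[at["group"] == study.vehicle_group]["volume_mm3"]
    trt = at[at["group"] == group]["volume_mm3"]
    if veh.empty:
        raise ValueError(
            f"no uncensored vehicle animals at day {day}; choose an earlier reference day"
        )
    if trt.empty:
        raise ValueError(f"no uncensored animals in group {group!r} at day {day}")
    veh_mean = float(veh.mean())
    if veh_mean == 0:
        raise ValueError("vehicle mean volume is zero")
    ratio = float(trt.mean()) / veh_mean
    p = sig = None
    if with_significance and group != study.vehicle_group:
        pvals = anova_tukey(study, day)
        p = pvals.get(group)
        sig = None if p is None else bool(p < 0.05)
    return TCResult(group, day, ratio, p, sig, len(trt), len(veh))


def anova_tukey(study: EfficacyStudy, reference_day: float | None = None) -> dict[str, float]:
    """Tukey HSD adjusted p-values of each arm vs vehicle at the reference day.

    One-way ANOVA structure across all arms on that day's uncensored volumes;
    pairs not involving the vehicle arm are computed but not returned.
    """
    day = study.default_reference_day() if reference_day is None else reference_day
    at = study.uncensored_at(day)
    counts = at.groupby("group")["volume_mm3"].size()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >=2 groups with >=2 animals each at the reference day")
    if at.groupby("group")["volume_mm3"].var(ddof=1).fillna(0).eq(0).all():
        raise ValueError("degenerate data: zero within-group variance everywhere")
    res = pairwise_tukeyhsd(
        at["volume_mm3"].to_numpy(float), at["group"].to_numpy(str), alpha=0.05
    )
    out: dict[str, float] = {}
    pairs = list(itertools.combinations(res.groupsunique, 2))
    for (g1, g2), p in zip(pairs, np.atleast_1d(res.pvalues)):
        pair = {str(g1), str(g2)}
        if study.vehicle_group in pair:
            other = (pair - {study.vehicle_group}).pop()
            out[other] = float(p)
    return out


def _validate_tc(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.5:
        raise ValueError(f"{name} T/C = {value:g} outside the plausible range [0, 1.5]")
    if value > 1.0:
        warnings.warn(f"{name} T/C = {value:g} > 1 clamped to 1 for the Bliss null", stacklevel=3)
        return 1.0
    return value


def bliss_expected(a_tc: float, b_tc: float, convention: str = INHIBITION_SCALE) -> float:
    """Expected additive combination T/C under Bliss independence."""
    a = _validate_tc(a_tc, "drug A")
    b = _validate_tc(b_tc, "drug B")
    if convention == INHIBITION_SCALE:
        return a * b
    if convention == TC_LITERAL:
        return a + b - a * b
    raise ValueError(f"unknown Bliss convention {convention!r}")


def bliss_call(
    expected_tc: float,
    observed_tc: float,
    margin: float = 0.10,
    a_tc: float = float("nan"),
    b_tc: float = float("nan"),
    convention: str = INHIBITION_SCALE,
) -> BlissCall:
    """Classify a combination arm against its Bliss-expected T/C.

    ``margin`` is in absolute T/C units; observed more than ``margin`` below
    the expectation is synergistic, more than ``margin`` above antagonistic,
    boundary values additive.
    """
    if not 0.0 < margin <= 0.5:
        raise ValueError("margin must lie in (0, 0.5]")
    eps = 1e-9  # keep exact-boundary cases additive despite float rounding
    if observed_tc < expected_tc - margin - eps:
        call = "synergistic"
    elif observed_tc > expected_tc + margin + eps:
        call = "antagonistic"
    else:
        call = "additive"
    return BlissCall(a_tc, b_tc, expected_tc, observed_tc, margin, call, convention)


def bliss_table(
    tc_by_arm: dict[tuple[float, float], float],
    margin: float = 0.10,
    convention: str = INHIBITION_SCALE,
) -> pd.DataFrame:
    """Bliss synergy calls for every combination arm in a T/C table.

    ``tc_by_arm`` maps (ttc_dose, olaparib_dose) to the arm's T/C at a common
    reference day; monotherapy arms have one zero dose. Every combination arm
    must have both of its monotherapy counterparts present (same study, same
    day) or a KeyError is raised.
    """
    rows = []
    for (da, db), observed in sorted(tc_by_arm.items()):
        if da <= 0 or db <= 0:
            continue
        try:
            a = tc_by_arm[(da, 0.0)]
            b = tc_by_arm[(0.0, db)]
        except KeyError as exc:
            raise KeyError(
                f"combination ({da:g}, {db:g}) lacks monotherapy arm {exc} at the same day"
            ) from None
        exp = bliss_expected(a, b, convention)
        call = bliss_call(exp, observed, margin, a, b, convention)
        rows.append(
            {
                "ttc_dose": da,
                "olaparib_dose": db,
                "a_tc": a,
                "b_tc": b,
                "expected_tc": exp,
                "observed_tc": observed,
                "call": call.call,
                "convention": convention,
                "margin": margin,
            }
        )
    return pd.DataFrame(rows)


def study_bliss_table(
    study: EfficacyStudy,
    reference_day: float | None = None,
    margin: float = 0.10,
    convention: str = INHIBITION_SCALE,
) -> pd.DataFrame:
    """Bliss table computed from a study's own arms via :func:`tc_ratio`.

    Requires ``study.arm_doses``; all T/C values come from the same reference
    day (mixing days is structurally impossible here).
    """
    if not study.arm_doses:
        raise ValueError("study.arm_doses must map group labels to (ttc, olaparib) doses")
    day = study.default_reference_day() if reference_day is None else reference_day
    tc_by_arm = {
        doses: tc_ratio(study, group, day, with_significance=False).t_over_c
        for group, doses in study.arm_doses.items()
        if group != study.vehicle_group
    }
    return bliss_table(tc_by_arm, margin=margin, convention=convention)
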