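"""Hematology time-series summaries: nadir depth/day and recovery day.

Counts are expressed as a fraction of the pre-dose baseline. Baseline
samples taken a day or two before dosing are treated as day-0 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LINEAGE_COLUMNS", "NadirResult", "hematology_nadir", "hematology_recovery",
           "hematology_summary"]

LINEAGE_COLUMNS = {
    "platelets": "platelets_1e9_per_l",
    "wbc": "wbc_1e9_per_l",
    "rbc": "rbc_1e12_per_l",
}


@dataclass
class NadirResult:
    day: float
    fraction_of_baseline: float
    baseline: float
    suppressed: bool  # False when the series never drops below baseline


def _baseline(days: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Baseline (day, count): earliest pre-dose sample, mapped to day 0."""
    i = int(np.argmin(days))
    if days[i] > 0:
        raise ValueError("no baseline measurement at or before day 0")
    return 0.0, float(counts[i])


def hematology_nadir(days, counts) -> NadirResult:
    """Minimum of the series as fraction of baseline, with its day.

    A series that never drops below baseline reports the baseline day with
    fraction 1.0 and ``suppressed=False``.
    """
    days = np.asarray(days, float)
    counts = np.asarray(counts, float)
    if np.any(counts <= 0):
        raise ValueError("cell counts must be positive")
    base_day, base = _baseline(days, counts)
    i = int(np.argmin(counts))
    frac = float(counts[i] / base)
    if frac >= 1.0:
        return NadirResult(base_day, 1.0, base, False)
    return NadirResult(float(max(days[i], 0.0)), frac, base, True)


def hematology_recovery(days, counts, tolerance: float = 0.1) -> float | None:
    """First post-nadir day with count >= (1 - tolerance) x baseline.

    Returns None when the series never recovers within the sampled window.
    """
    days = np.asarray(days, float)
    counts = np.asarray(counts, float)
    nadir = hematology_nadir(days, counts)
    if not nadir.suppressed:
        return nadir.day
    after = (days > nadir.day) & (counts >= (1.0 - tolerance) * nadir.baseline)
    if not after.any():
        return None
    return float(days[after].min())


def hematology_summary(
    df: pd.DataFrame, tolerance: float = 0.1
) -> pd.DataFrame:
    """Group-level nadir/recovery per lineage from a hematology table.

    Per group and lineage the animal counts are averaged per day first, then
    the nadir and recovery rules run on the mean series.
    """
    rows = []
    for group, sub in df.groupby("group"):
        for lineage, col in LINEAGE_COLUMNS.items():
            series = sub.groupby("day")[col].mean()
            nadir = hematology_nadir(series.index.to_numpy(), series.to_numpy())
            rec = hematology_recovery(series.index.to_numpy(), series.to_numpy(), tolerance)
            rows.append(
                {
                    "group": group,
                    "lineage": lineage,
                    "nadir_day": nadir.day,
                    "nadir_fraction": nadir.fraction_of_baseline,
                    "suppressed": nadir.suppressed,
                    "recovery_day": rec,
                }
            )
    return pd.DataFrame(rows)
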