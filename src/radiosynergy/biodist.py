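"""Biodistribution arithmetic: %IA/g and tumor-to-blood ratios.

Organ counts from the gamma detector arrive as activities at harvest time;
they are decay-corrected to injection time and normalized to the injected
activity and sample mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nuclides import TH227, Nuclide, decay_correct


@dataclass(frozen=True)
class ActivityMeasurement:
    """One harvested sample: activity at measurement time plus its metadata."""

    sample: str
    time_h: float
    activity_bq: float
    mass_g: float
    injected_bq: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("sample mass must be positive")
        if self.activity_bq < 0:
            raise ValueError("activity must be non-negative")
        if self.injected_bq <= 0:
            raise ValueError("injected activity must be positive")


def percent_ia_per_gram(m: ActivityMeasurement, nuclide: Nuclide = TH227) -> float:
    """Percent of injected activity per gram of tissue, decay-corrected.

    The measured counts are corrected back to injection time, divided by the
    injected activity and sample mass, and expressed in percent. Linear in
    measured activity, inversely linear in mass.
    """
    corrected = decay_correct(m.activity_bq, m.time_h, nuclide)
    return corrected / m.injected_bq / m.mass_g * 100.0


def biodist_table(df: pd.DataFrame, nuclide: Nuclide = TH227) -> pd.DataFrame:
    """Per-sample %IA/g for a validated biodistribution table.

    Expects columns animal_id, group, organ, time_h, activity_bq, mass_g,
    injected_bq; returns the same rows with a ``percent_ia_per_g`` column.
    """
    out = df.copy()
    factor = 2.0 ** (out["time_h"].to_numpy(float) / nuclide.half_life_h)
    out["percent_ia_per_g"] = (
        out["activity_bq"].to_numpy(float)
        * factor
        / out["injected_bq"].to_numpy(float)
        / out["mass_g"].to_numpy(float)
        * 100.0
    )
    return out


def summarize_biodist(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/n of %IA/g by group, organ and time."""
    g = per_sample.groupby(["group", "organ", "time_h"])["percent_ia_per_g"]
    out = g.agg(mean="mean", sd="std", n="size").reset_index()
    return out.sort_values(["group", "organ", "time_h"]).reset_index(drop=True)


def tumor_to_blood(per_sample: pd.DataFrame, time_h: float, group: str | None = None) -> float:
    """Ratio of mean tumor %IA/g to mean blood %IA/g at one harvest time.

    Returns ``nan`` (with a zero-blood guard) if blood activity is zero.
    """
    df = per_sample
    if group is not None:
        df = df[df["group"] == group]
    at_t = df[np.isclose(df["time_h"].astype(float), time_h)]
    tumor = at_t.loc[at_t["organ"] == "tumor", "percent_ia_per_g"]
    blood = at_t.loc[at_t["organ"] == "blood", "percent_ia_per_g"]
    if tumor.empty or blood.empty:
        raise ValueError(f"no tumor and blood entries at t = {time_h} h")
    b = float(blood.mean())
    if b == 0:
        return float("nan")
    return float(tumor.mean()) / b
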