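"""CSV schemas, validation with row-level error reports, and table -> domain
object converters."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .combination import FixedRatioDesign
from .dose_response import DoseResponseCurve, normalize_viability


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # "number" | "int" | "str" | "bool"
    min: float | None = None
    max: float | None = None
    nullable: bool = False


SCHEMAS: dict[str, tuple[Column, ...]] = {
    "plates": (
        Column("well", "str"),
        Column("agent_a_conc", "number", min=0.0),
        Column("agent_b_conc", "number", min=0.0),
        Column("mixture_weight_a", "number", min=0.0, max=1.0, nullable=True),
        Column("raw_signal", "number"),
        Column("is_control", "bool"),
        Column("is_blank", "bool"),
    ),
    "tumor_volumes": (
        Column("animal_id", "str"),
        Column("group", "str"),
        Column("day", "number", min=0.0),
        Column("volume_mm3", "number", min=0.0),
        Column("body_weight_g", "number", min=0.0),
    ),
    "hematology": (
        Column("animal_id", "str"),
        Column("group", "str"),
        Column("day", "number"),
        Column("platelets_1e9_per_l", "number", min=0.0),
        Column("wbc_1e9_per_l", "number", min=0.0),
        Column("rbc_1e12_per_l", "number", min=0.0),
    ),
    "biodistribution": (
        Column("animal_id", "str"),
        Column("group", "str"),
        Column("organ", "str"),
        Column("time_h", "number", min=0.0),
        Column("activity_bq", "number", min=0.0),
        Column("mass_g", "number"),
        Column("injected_bq", "number"),
    ),
}

# strictly-positive columns get their own range rule
_POSITIVE = {("biodistribution", "mass_g"), ("biodistribution", "injected_bq")}


@dataclass
class ValidationReport:
    schema: str
    path: str
    errors: list[str] = field(default_factory=list)
    table: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> pd.DataFrame:
        if self.errors:
            listing = "\n  ".join(self.errors)
            raise ValueError(f"{self.path} failed {self.schema!r} validation:\n  {listing}")
        assert self.table is not None
        return self.table


def validate_table(df: pd.DataFrame, schema_id: str, path: str = "<memory>") -> ValidationReport:
    """Type/range checks per schema; errors carry 1-based data row numbers."""
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}; have {sorted(SCHEMAS)}")
    report = ValidationReport(schema_id, path)
    cols = SCHEMAS[schema_id]
    missing = [c.name for c in cols if c.name not in df.columns]
    if missing:
        report.errors = [f"missing column(s): {', '.join(missing)}"]
        return report
    out = df.copy()
    for c in cols:
        s = out[c.name]
        if c.kind in ("number", "int"):
            coerced = pd.to_numeric(s, errors="coerce")
            bad = coerced.isna() & s.notna()
            for i in np.flatnonzero(bad.to_numpy()):
                report.errors.append(f"row {i + 1}: non-numeric {c.name}={s.iloc[i]!r}")
            if not c.nullable:
                for i in np.flatnonzero(coerced.isna().to_numpy() & ~bad.to_numpy()):
                    report.errors.append(f"row {i + 1}: missing {c.name}")
            lo = c.min
            if (schema_id, c.name) in _POSITIVE:
                lo = np.nextafter(0.0, 1.0)
            if lo is not None:
                for i in np.flatnonzero((coerced < lo).to_numpy()):
                    report.errors.append(
                        f"row {i + 1}: {c.name}={coerced.iloc[i]:g} below minimum {c.min:g}"
                        if (schema_id, c.name) not in _POSITIVE
                        else f"row {i + 1}: {c.name}={coerced.iloc[i]:g} must be positive"
                    )
            if c.max is not None:
                for i in np.flatnonzero((coerced > c.max).to_numpy()):
                    report.errors.append(
                        f"row {i + 1}: {c.name}={coerced.iloc[i]:g} above maximum {c.max:g}"
                    )
            out[c.name] = coerced
        elif c.kind == "bool":
            mapped = s.map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
                 "true": True, "false": False}
            )
            for i in np.flatnonzero(mapped.isna().to_numpy()):
                report.errors.append(f"row {i + 1}: non-boolean {c.name}={s.iloc[i]!r}")
            out[c.name] = mapped.astype("boolean").fillna(False).astype(bool)
    report.table = out
    return report


def validate_csv(path: str | Path, schema_id: str) -> ValidationReport:
    """Read and validate a CSV file against one of the pipeline schemas."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_table(df, schema_id, str(path))


def curves_from_plates(
    df: pd.DataFrame,
    agent_a: str = "agent A",
    agent_b: str = "agent B",
) -> tuple[DoseResponseCurve, DoseResponseCurve, FixedRatioDesign, list[DoseResponseCurve]]:
    """Split a validated plates table into single-agent and mixture curves.

    Raw signals are normalized to fraction-of-control viability using the
    plate's own control and blank wells. Mixture wells are keyed by their
    weight; the mixture dose axis is reconstructed as the fraction of the
    top concentrations (agent_a_conc / (w_A · top_A)).
    """
    controls = df[df["is_control"]]["raw_signal"]
    blanks = df[df["is_blank"]]["raw_signal"]
    if controls.empty or blanks.empty:
        raise ValueError("plates table must contain control and blank wells")
    treated = df[~df["is_control"] & ~df["is_blank"]].copy()
    treated["viability"] = normalize_viability(treated["raw_signal"], controls, blanks)

    is_mix = treated["mixture_weight_a"].notna()
    solo_a = treated[~is_mix & (treated["agent_a_conc"] > 0)]
    solo_b = treated[~is_mix & (treated["agent_b_conc"] > 0)]
    if solo_a.empty or solo_b.empty:
        raise ValueError("plates table lacks single-agent titrations")
    top_a = float(solo_a["agent_a_conc"].max())
    top_b = float(solo_b["agent_b_conc"].max())
    curve_a = DoseResponseCurve(agent_a, solo_a["agent_a_conc"].to_numpy(),
                                solo_a["viability"].to_numpy())
    curve_b = DoseResponseCurve(agent_b, solo_b["agent_b_conc"].to_numpy(),
                                solo_b["viability"].to_numpy())

    weights = sorted(treated.loc[is_mix, "mixture_weight_a"].unique(), reverse=True)
    mixtures: list[DoseResponseCurve] = []
    for wa in weights:
        sub = treated[is_mix & (treated["mixture_weight_a"] == wa)]
        frac = sub["agent_a_conc"].to_numpy() / (wa * top_a)
        mixtures.append(
            DoseResponseCurve(f"mix {wa:.1f}:{1 - wa:.1f}", frac,
                              sub["viability"].to_numpy(), unit="fraction")
        )
    design = FixedRatioDesign(
        top_a, top_b, weights=tuple((float(w), float(round(1.0 - w, 10))) for w in weights)
    )
    return curve_a, curve_b, design, mixtures


def load_reported_tc_table() -> pd.DataFrame:
    """The published treatment-over-control summary shipped with the package.

    One row per treatment arm and tumor model (parental vs BRCA2-knockout),
    with the reported T/C at the study's reference day and its significance
    flag. These printed values are the worked-example input for the Bliss
    synergy calls.
    """
    with resources.files("radiosynergy.data").joinpath("reported_tc_ratios.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
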