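"""Run configuration and the end-to-end report pipeline.

The pipeline ties the stages together: validate input CSVs, fit in vitro
curves and score the combination index, compute in vivo T/C + significance
+ Bliss calls, summarize biodistribution and hematology, and write JSON/CSV
reports with full provenance. All numerical work lives in the other
modules; this layer only routes data.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biodist import biodist_table, summarize_biodist, tumor_to_blood
from .combination import combination_index, isobologram_points
from .dose_response import fit_4pl, fit_median_effect
from .efficacy import (
    INHIBITION_SCALE,
    EfficacyStudy,
    anova_tukey,
    group_doubling_time,
    study_bliss_table,
    tc_ratio,
)
from .hematology import hematology_summary
from .io import curves_from_plates, validate_csv
from .nuclides import get_nuclide

_ARM_RE = re.compile(r"(?:ttc-(?P<ttc>[\d.]+))?\+?(?:ola-(?P<ola>[\d.]+))?$")


def parse_arm_doses(groups) -> dict[str, tuple[float, float]]:
    """Doses from arm labels of the form ``ttc-<kBq/kg>``, ``ola-<mg/kg>``,
    ``ttc-<x>+ola-<y>`` or ``vehicle``."""
    out: dict[str, tuple[float, float]] = {}
    for g in groups:
        if g == "vehicle":
            out[g] = (0.0, 0.0)
            continue
        m = _ARM_RE.fullmatch(g)
        if not m or (m.group("ttc") is None and m.group("ola") is None):
            raise ValueError(f"cannot parse doses from group label {g!r}")
        out[g] = (float(m.group("ttc") or 0.0), float(m.group("ola") or 0.0))
    return out


@dataclass
class RunConfig:
    """Defaults reproduce the study-default analysis: inhibition-scale Bliss
    with a 0.10 margin, CI at the 50% effect level, Th-227 at 18.7 days."""

    plates: str | None = None
    tumor_volumes: str | None = None
    hematology: str | None = None
    biodistribution: str | None = None
    bliss_convention: str = INHIBITION_SCALE
    bliss_margin: float = 0.10
    ci_effect_level: float = 0.5
    reference_day: float | None = None
    nuclide_overrides: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if hasattr(x, "item"):
        return x.item()
    return x


def analyze_plates(path: str | Path, effect_level: float = 0.5) -> dict:
    """Fit both single agents and all mixtures; return the CI report dict."""
    table = validate_csv(path, "plates").raise_if_invalid()
    curve_a, curve_b, design, mixtures = curves_from_plates(table)
    fit_a4, fit_b4 = fit_4pl(curve_a), fit_4pl(curve_b)
    me_a, me_b = fit_median_effect(curve_a), fit_median_effect(curve_b)
    ci = combination_index(design, me_a, me_b, mixtures, effect_level=effect_level)
    iso = isobologram_points(fit_a4, fit_b4, ci)
    return {
        "fits": {
            "agent_a": {"4pl": _fit_dict(fit_a4), "median_effect": _me_dict(me_a)},
            "agent_b": {"4pl": _fit_dict(fit_b4), "median_effect": _me_dict(me_b)},
        },
        "per_ratio_ci": [
            {
                "weight_a": r.weight_a,
                "weight_b": r.weight_b,
                "ci": r.ci,
                "dose_a": r.dose_a,
                "dose_b": r.dose_b,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in ci.per_ratio
        ],
        "average_ci": ci.average_ci,
        "classification": ci.classification,
        "effect_level": ci.effect_level,
        "n_excluded_ratios": ci.n_excluded,
        "isobologram": [
            {"dose_a": p.dose_a, "dose_b": p.dose_b, "effect_level": p.effect_level}
            for p in iso
        ],
    }


def _fit_dict(f) -> dict:
    return {
        "top": f.top,
        "bottom": f.bottom,
        "hill": f.hill,
        "ec50": f.ec50,
        "absolute_ic50": f.absolute_ic50,
        "ic50_status": f.ic50_status.value,
        "residual_sse": f.residual_sse,
    }


def _me_dict(f) -> dict:
    return {"dm": f.dm, "m": f.m, "r_squared": f.r_squared, "n_points": f.n_points}


def analyze_efficacy(
    path: str | Path,
    reference_day: float | None = None,
    margin: float = 0.10,
    convention: str = INHIBITION_SCALE,
) -> dict:
    """T/C per arm with Tukey p-values, doubling times, and the Bliss table."""
    table = validate_csv(path, "tumor_volumes").raise_if_invalid()
    study = EfficacyStudy(table, arm_doses=parse_arm_doses(sorted(table["group"].unique())))
    day = study.default_reference_day() if reference_day is None else reference_day
    pvals = anova_tukey(study, day)
    tc = {}
    for g in study.groups():
        if g == study.vehicle_group:
            continue
        r = tc_ratio(study, g, day, with_significance=False)
        tc[g] = {
            "t_over_c": r.t_over_c,
            "p_value": pvals.get(g),
            "significant": bool(pvals[g] < 0.05) if g in pvals else None,
            "n": r.n_treated,
        }
    doubling = {}
    for g in study.groups():
        td, n = group_doubling_time(study, g)
        doubling[g] = {"days": td, "n_animals": n}
    bliss = study_bliss_table(study, day, margin=margin, convention=convention)
    return {
        "reference_day": day,
        "t_over_c": tc,
        "doubling_time": doubling,
        "bliss": bliss.to_dict(orient="records"),
    }


def analyze_biodistribution(path: str | Path, nuclide_overrides: dict | None = None) -> dict:
    table = validate_csv(path, "biodistribution").raise_if_invalid()
    nuclide = get_nuclide("Th-227", nuclide_overrides or {})
    per_sample = biodist_table(table, nuclide)
    summary = summarize_biodist(per_sample)
    ratios = {}
    for group in sorted(per_sample["group"].unique()):
        sub = per_sample[per_sample["group"] == group]
        for t in sorted(sub["time_h"].unique()):
            organs = set(sub[sub["time_h"] == t]["organ"])
            if {"tumor", "blood"} <= organs:
                ratios[f"{group}@{t:g}h"] = tumor_to_blood(per_sample, t, group)
    return {
        "summary": summary.to_dict(orient="records"),
        "tumor_to_blood": ratios,
        "_summary_frame": summary,
    }


def analyze_hematology(path: str | Path, tolerance: float = 0.1) -> dict:
    table = validate_csv(path, "hematology").raise_if_invalid()
    summary = hematology_summary(table, tolerance)
    return {"summary": summary.to_dict(orient="records")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage with an input path set; write reports to outdir.

    Returns the report bundle; files written are ``ci_report.json``,
    ``isobologram.csv``, ``efficacy_report.json``, ``biodist_report.csv``,
    ``hematology_report.json`` and ``provenance.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not any([config.plates, config.tumor_volumes, config.hematology, config.biodistribution]):
        raise ValueError("no inputs configured: set at least one input path")
    bundle: dict = {
        "provenance": {
            "package": "radiosynergy",
            "version": __version__,
            "seed": config.seed,
            "config": _jsonable(asdict(config)),
        }
    }
    if config.plates:
        ci = analyze_plates(config.plates, config.ci_effect_level)
        bundle["ci"] = ci
        (outdir / "ci_report.json").write_text(json.dumps(_jsonable(ci), indent=2))
        pd.DataFrame(ci["isobologram"]).to_csv(outdir / "isobologram.csv", index=False)
    if config.tumor_volumes:
        eff = analyze_efficacy(
            config.tumor_volumes, config.reference_day, config.bliss_margin,
            config.bliss_convention,
        )
        bundle["efficacy"] = eff
        (outdir / "efficacy_report.json").write_text(json.dumps(_jsonable(eff), indent=2))
    if config.biodistribution:
        bio = analyze_biodistribution(config.biodistribution, config.nuclide_overrides)
        bio["_summary_frame"].to_csv(outdir / "biodist_report.csv", index=False)
        bundle["biodistribution"] = {k: v for k, v in bio.items() if not k.startswith("_")}
    if config.hematology:
        heme = analyze_hematology(config.hematology)
        bundle["hematology"] = heme
        (outdir / "hematology_report.json").write_text(json.dumps(_jsonable(heme), indent=2))
    (outdir / "provenance.json").write_text(json.dumps(_jsonable(bundle["provenance"]), indent=2))
    return bundle
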