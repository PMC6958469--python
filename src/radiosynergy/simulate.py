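"""Seed-reproducible synthetic datasets with the statistical structure the
analysis assumes.

Four generators mirror the four experiment types:

* viability plates — single-agent 4PL curves plus nine fixed-ratio mixtures
  whose survival surface is ``(sA·sB)^γ``: γ = 1 is exactly Bliss-independent,
  γ > 1 synergistic, γ < 1 antagonistic. Additive Gaussian noise on the
  viability fraction.
* xenograft study — exponential growth with dose-dependent log-kill terms
  (radioconjugate kill decaying with the Th-227 half-life; a constant
  PARP-inhibitor kill during the dosing window), an interaction multiplier ψ
  on the combined kill, multiplicative lognormal measurement noise, and
  humane-endpoint censoring at 1,500 mm³.
* biodistribution — analytic tumor uptake (saturating exponential) and
  bi-exponential blood clearance in decay-corrected %IA/g units, emitted as
  raw (decayed, noisy) detector activities.
* hematology — programmed nadir/recovery dips per lineage.

Every generator is a pure function of its spec (seed included): identical
specs give identical tables. Each returns a ``truth`` sidecar holding the
programmed ground truth that downstream recovery tests check against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combination import NINE_RATIO_WEIGHTS
from .nuclides import LN2, TH227

__all__ = [
    "Agent4PL",
    "PlateSimSpec",
    "ArmSpec",
    "XenoSimSpec",
    "BiodistSimSpec",
    "HemeSimSpec",
    "gen_viability_plates",
    "gen_xenograft_study",
    "gen_biodistribution",
    "gen_hematology",
    "ttc_kill_rate",
    "ola_kill_rate",
]

_TH227_LAMBDA_PER_DAY = LN2 / 18.7


# ---------------------------------------------------------------------------
# viability plates


@dataclass(frozen=True)
class Agent4PL:
    """Ground-truth 4PL parameters of one agent."""

    label: str
    ec50: float
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0
    unit: str = ""

    def survival(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, float)
        with np.errstate(divide="ignore"):
            ratio = np.where(d > 0, d / self.ec50, 0.0)
            s = self.bottom + (self.top - self.bottom) / (1.0 + ratio**self.hill)
        return np.where(d == 0, self.top, s)


@dataclass(frozen=True)
class PlateSimSpec:
    """Fixed-ratio combination plate: two titrations plus nine mixtures.

    Defaults emulate the study design: radioconjugate titrated 0.01–50
    kBq/mL, PARP inhibitor 0.01–25 µM, nine weight pairs 0.9:0.1 … 0.1:0.9,
    3 replicates, 5% additive viability noise. The default potencies are the
    reported parental-line IC50s (22 kBq/mL, 5 µM) with unit hill slopes.
    """

    agent_a: Agent4PL = Agent4PL("HER2-TTC", 22.0, 1.0, unit="kBq/mL")
    agent_b: Agent4PL = Agent4PL("olaparib", 5.0, 1.0, unit="uM")
    top_a: float = 50.0
    top_b: float = 25.0
    min_a: float = 0.01
    min_b: float = 0.01
    n_points: int = 9
    weights: tuple[tuple[float, float], ...] = NINE_RATIO_WEIGHTS
    gamma: float = 1.0
    noise_sd: float = 0.05
    replicates: int = 3
    n_controls: int = 8
    n_blanks: int = 8
    control_signal: float = 1000.0
    blank_signal: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("interaction exponent gamma must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def mixture_survival(self, fraction: np.ndarray, weight_a: float) -> np.ndarray:
        """Noise-free combination survival at fraction f of the top concentrations."""
        f = np.asarray(fraction, float)
        sa = self.agent_a.survival(weight_a * f * self.top_a)
        sb = self.agent_b.survival((1.0 - weight_a) * f * self.top_b)
        return (sa * sb) ** self.gamma


def _signal(spec: PlateSimSpec, viability: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = viability + rng.normal(0.0, spec.noise_sd, size=np.shape(viability))
    v = np.clip(v, 0.0, 1.2)
    return spec.blank_signal + v * (spec.control_signal - spec.blank_signal)


def gen_viability_plates(spec: PlateSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate one combination experiment as raw plate-reader rows.

    Returns the table in the ``plates`` CSV schema (well, agent_a_conc,
    agent_b_conc, mixture_weight_a, raw_signal, is_control, is_blank) and a
    truth dict with the programmed parameters.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    w = 0

    def add(conc_a, conc_b, weight_a, signal, is_control=False, is_blank=False):
        nonlocal w
        w += 1
        rows.append(
            {
                "well": f"w{w:04d}",
                "agent_a_conc": conc_a,
                "agent_b_conc": conc_b,
                "mixture_weight_a": weight_a,
                "raw_signal": round(float(signal), 6),
                "is_control": is_control,
                "is_blank": is_blank,
            }
        )

    for _ in range(spec.n_controls):
        add(0.0, 0.0, np.nan, _signal(spec, np.asarray(1.0), rng), is_control=True)
    for _ in range(spec.n_blanks):
        noise = rng.normal(0.0, spec.noise_sd) * (spec.control_signal - spec.blank_signal)
        add(0.0, 0.0, np.nan, spec.blank_signal + noise, is_blank=True)

    grid_a = np.geomspace(spec.min_a, spec.top_a, spec.n_points)
    grid_b = np.geomspace(spec.min_b, spec.top_b, spec.n_points)
    f_min = max(spec.min_a / spec.top_a, spec.min_b / spec.top_b)
    grid_f = np.geomspace(f_min, 1.0, spec.n_points)

    for _ in range(spec.replicates):
        for d in grid_a:
            add(d, 0.0, np.nan, _signal(spec, spec.agent_a.survival(d), rng))
        for d in grid_b:
            add(0.0, d, np.nan, _signal(spec, spec.agent_b.survival(d), rng))
        for wa, wb in spec.weights:
            surv = spec.mixture_survival(grid_f, wa)
            sig = _signal(spec, surv, rng)
            for f, s in zip(grid_f, sig):
                add(wa * f * spec.top_a, wb * f * spec.top_b, wa, s)

    truth = {
        "gamma": spec.gamma,
        "agent_a": {"ec50": spec.agent_a.ec50, "hill": spec.agent_a.hill,
                    "top": spec.agent_a.top, "bottom": spec.agent_a.bottom},
        "agent_b": {"ec50": spec.agent_b.ec50, "hill": spec.agent_b.hill,
                    "top": spec.agent_b.top, "bottom": spec.agent_b.bottom},
        "top_a": spec.top_a,
        "top_b": spec.top_b,
        "weights": list(spec.weights),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# xenograft study


def ttc_kill_rate(dose_kbq_kg: float, target_tc: float, day: float) -> float:
    """Radioconjugate kill-rate coefficient giving a chosen true T/C at ``day``.

    The instantaneous kill is k·dose·exp(−λt) with λ the Th-227 decay
    constant, so the integrated log-kill at t is k·dose·(1−exp(−λt))/λ.
    """
    integral = (1.0 - math.exp(-_TH227_LAMBDA_PER_DAY * day)) / _TH227_LAMBDA_PER_DAY
    return -math.log(target_tc) / (dose_kbq_kg * integral)


def ola_kill_rate(dose_mg_kg: float, target_tc: float, day: float, window: float = 28.0) -> float:
    """PARP-inhibitor kill-rate coefficient giving a chosen true T/C at ``day``."""
    return -math.log(target_tc) / (dose_mg_kg * min(day, window))


# defaults anchored mid-dose: 300 kBq/kg and 50 mg/kg each halve the tumor
# burden relative to vehicle by day 21
_K_TTC_DEFAULT = ttc_kill_rate(300.0, 0.5, 21.0)
_K_OLA_DEFAULT = ola_kill_rate(50.0, 0.5, 21.0)


@dataclass(frozen=True)
class ArmSpec:
    name: str
    ttc_kbq_kg: float = 0.0
    olaparib_mg_kg: float = 0.0
    psi: float = 1.0  # interaction multiplier on the combined kill
    n: int = 10


_STUDY_ARMS: tuple[ArmSpec, ...] = (
    ArmSpec("vehicle"),
    ArmSpec("ttc-125", ttc_kbq_kg=125.0),
    ArmSpec("ttc-300", ttc_kbq_kg=300.0),
    ArmSpec("ttc-600", ttc_kbq_kg=600.0),
    ArmSpec("ola-25", olaparib_mg_kg=25.0),
    ArmSpec("ola-50", olaparib_mg_kg=50.0),
    ArmSpec("ttc-125+ola-25", 125.0, 25.0),
    ArmSpec("ttc-125+ola-50", 125.0, 50.0),
    ArmSpec("ttc-300+ola-25", 300.0, 25.0),
    ArmSpec("ttc-300+ola-50", 300.0, 50.0),
)


@dataclass(frozen=True)
class XenoSimSpec:
    """Xenograft efficacy study: exponential growth minus dose-dependent kill.

    Defaults follow the study design: randomization at 90 mm³ average tumor
    volume, vehicle doubling time 8.3 days, single radioconjugate dose at day
    0 (kill decaying with the 18.7-day half-life), daily PARP inhibitor for a
    28-day window, 10 animals per arm measured twice weekly, censoring at
    1,500 mm³. ψ = 1 on every default arm (no programmed interaction); set
    ``psi`` on a combination arm to emulate the BRCA2-deficient setting.
    """

    initial_volume_mm3: float = 90.0
    doubling_time_d: float = 8.3
    k_ttc: float = _K_TTC_DEFAULT
    k_ola: float = _K_OLA_DEFAULT
    ola_window_d: float = 28.0
    arms: tuple[ArmSpec, ...] = _STUDY_ARMS
    days: tuple[float, ...] = (0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35, 38)
    noise_sd: float = 0.1
    endpoint_mm3: float = 1500.0
    body_weight_g: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.days:
            raise ValueError("measurement days must not be empty")

    @property
    def growth_per_day(self) -> float:
        return LN2 / self.doubling_time_d

    def log_kill(self, arm: ArmSpec, t: np.ndarray) -> np.ndarray:
        """Integrated log-kill ψ·(K_ttc(t) + K_ola(t)) for one arm."""
        t = np.asarray(t, float)
        k1 = (
            self.k_ttc
            * arm.ttc_kbq_kg
            * (1.0 - np.exp(-_TH227_LAMBDA_PER_DAY * t))
            / _TH227_LAMBDA_PER_DAY
        )
        k2 = self.k_ola * arm.olaparib_mg_kg * np.minimum(t, self.ola_window_d)
        return arm.psi * (k1 + k2)

    def true_volume(self, arm: ArmSpec, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.initial_volume_mm3 * np.exp(self.growth_per_day * t - self.log_kill(arm, t))

    def true_tc(self, arm: ArmSpec, day: float) -> float:
        """Model-true T/C at ``day`` (noise-free, ignoring censoring)."""
        return float(np.exp(-self.log_kill(arm, np.asarray(day, float))))


def gen_xenograft_study(spec: XenoSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate tumor volumes per animal; returns (volumes, censor log, truth)."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.days, float)
    rows: list[dict] = []
    censored: list[dict] = []
    for arm in spec.arms:
        true_v = spec.true_volume(arm, t)
        for i in range(arm.n):
            animal = f"{arm.name}-{i + 1:02d}"
            noise = np.exp(rng.normal(0.0, spec.noise_sd, size=t.size))
            v = true_v * noise
            bw = spec.body_weight_g * np.exp(rng.normal(0.0, 0.02, size=t.size))
            for j, day in enumerate(t):
                rows.append(
                    {
                        "animal_id": animal,
                        "group": arm.name,
                        "day": float(day),
                        "volume_mm3": round(float(v[j]), 3),
                        "body_weight_g": round(float(bw[j]), 3),
                    }
                )
                if v[j] >= spec.endpoint_mm3:
                    censored.append(
                        {
                            "animal_id": animal,
                            "day": float(day),
                            "reason": "tumor volume >= 1500 mm3",
                        }
                    )
                    break
    ref_day = float(max(spec.days))
    truth = {
        "doubling_time_d": spec.doubling_time_d,
        "k_ttc": spec.k_ttc,
        "k_ola": spec.k_ola,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "true_tc_day21": {a.name: spec.true_tc(a, 21.0) for a in spec.arms},
        "arm_doses": {a.name: [a.ttc_kbq_kg, a.olaparib_mg_kg] for a in spec.arms},
        "psi": {a.name: a.psi for a in spec.arms},
    }
    return pd.DataFrame(rows), pd.DataFrame(censored, columns=["animal_id", "day", "reason"]), truth


# ---------------------------------------------------------------------------
# biodistribution


@dataclass(frozen=True)
class BiodistSimSpec:
    """Tumor/blood activity time courses for targeted vs isotype antibody.

    Curves are in decay-corrected %IA/g units: tumor uptake saturates at
    ``tumor_plateau`` (targeted ~50, isotype ~5 %IA/g); blood clears
    bi-exponentially. The emitted table holds raw detector activities, i.e.
    the curves decayed with the Th-227 half-life plus lognormal noise.
    """

    mode: str = "targeted"  # "targeted" | "isotype"
    targeted_plateau: float = 50.0
    isotype_plateau: float = 5.0
    tumor_uptake_per_h: float = 0.02
    blood_a1: float = 12.0
    blood_half_t1_h: float = 10.0
    blood_a2: float = 20.0
    blood_half_t2_h: float = 150.0
    times_h: tuple[float, ...] = (24.0, 72.0, 168.0, 336.0)
    n_per_time: int = 3
    injected_bq: float = 15000.0
    tumor_mass_g: float = 0.3
    blood_mass_g: float = 0.2
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("targeted", "isotype"):
            raise ValueError("mode must be 'targeted' or 'isotype'")
        if self.isotype_plateau >= self.targeted_plateau:
            raise ValueError("isotype plateau must stay below the targeted plateau")

    @property
    def tumor_plateau(self) -> float:
        return self.targeted_plateau if self.mode == "targeted" else self.isotype_plateau

    def tumor_curve(self, t_h: np.ndarray) -> np.ndarray:
        t = np.asarray(t_h, float)
        return self.tumor_plateau * (1.0 - np.exp(-self.tumor_uptake_per_h * t))

    def blood_curve(self, t_h: np.ndarray) -> np.ndarray:
        t = np.asarray(t_h, float)
        return self.blood_a1 * 2.0 ** (-t / self.blood_half_t1_h) + self.blood_a2 * 2.0 ** (
            -t / self.blood_half_t2_h
        )

    def true_tumor_to_blood(self, t_h: float) -> float:
        return float(self.tumor_curve(np.asarray(t_h)) / self.blood_curve(np.asarray(t_h)))


def gen_biodistribution(spec: BiodistSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate harvested-sample activities; returns (table, truth)."""
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    rows: list[dict] = []
    organs = {
        "tumor": (spec.tumor_curve, spec.tumor_mass_g),
        "blood": (spec.blood_curve, spec.blood_mass_g),
    }
    animal = 0
    for t in spec.times_h:
        for _ in range(spec.n_per_time):
            animal += 1
            aid = f"{spec.mode}-{animal:02d}"
            for organ, (curve, mass) in organs.items():
                pct = float(curve(np.asarray(t)))
                decayed = pct / 100.0 * spec.injected_bq * mass * 2.0 ** (-t / TH227.half_life_h)
                noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                rows.append(
                    {
                        "animal_id": aid,
                        "group": spec.mode,
                        "organ": organ,
                        "time_h": float(t),
                        "activity_bq": round(decayed * noise, 6),
                        "mass_g": mass,
                        "injected_bq": spec.injected_bq,
                    }
                )
    truth = {
        "mode": spec.mode,
        "tumor_plateau": spec.tumor_plateau,
        "true_tumor_to_blood_336h": spec.true_tumor_to_blood(336.0),
        "true_tumor_pct_336h": float(spec.tumor_curve(np.asarray(336.0))),
        "seed": spec.seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# hematology


@dataclass(frozen=True)
class HemeSimSpec:
    """Myelosuppression curves: per-arm programmed dips per lineage.

    ``dips`` maps arm name -> lineage -> (nadir_day, depth, recovery_day)
    where depth is the fraction lost at nadir (0.5 = counts halve). The dip
    is an asymmetric Gaussian whose right width is chosen so the curve is
    back to (1 − recovery_tol)·baseline exactly at the programmed recovery
    day. Arms without dips stay at baseline in expectation.
    """

    baselines: tuple[tuple[str, float], ...] = (
        ("platelets", 1000.0),
        ("wbc", 8.0),
        ("rbc", 9.0),
    )
    dips: tuple[tuple[str, tuple[tuple[str, tuple[float, float, float]], ...]], ...] = (
        ("vehicle", ()),
        (
            "ttc-600",
            (
                ("platelets", (12.0, 0.5, 26.0)),
                ("wbc", (11.0, 0.5, 39.0)),
                ("rbc", (12.0, 0.05, 26.0)),
            ),
        ),
        (
            "ttc-120+ola-50",
            (("platelets", (12.0, 0.2, 26.0)), ("wbc", (11.0, 0.2, 39.0))),
        ),
    )
    sampling_days: tuple[float, ...] = (0.0, 14.0, 28.0, 42.0)
    n_per_arm: int = 10
    noise_cv: float = 0.05
    recovery_tol: float = 0.1
    seed: int = 0

    def curve(self, arm: str, lineage: str, t: np.ndarray) -> np.ndarray:
        base = dict(self.baselines)[lineage]
        dip = dict(dict(self.dips)[arm]).get(lineage)
        t = np.asarray(t, float)
        if dip is None:
            return np.full_like(t, base)
        nadir_day, depth, recovery_day = dip
        w_left = nadir_day / 3.0
        if depth > self.recovery_tol:
            w_right = (recovery_day - nadir_day) / math.sqrt(
                2.0 * math.log(depth / self.recovery_tol)
            )
        else:
            w_right = w_left
        w = np.where(t < nadir_day, w_left, w_right)
        return base * (1.0 - depth * np.exp(-((t - nadir_day) ** 2) / (2.0 * w**2)))


def gen_hematology(spec: HemeSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate blood counts per animal; returns (table, truth)."""
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    t = np.asarray(spec.sampling_days, float)
    col = {"platelets": "platelets_1e9_per_l", "wbc": "wbc_1e9_per_l", "rbc": "rbc_1e12_per_l"}
    rows: list[dict] = []
    for arm, _ in spec.dips:
        curves = {lin: spec.curve(arm, lin, t) for lin, _ in spec.baselines}
        for i in range(spec.n_per_arm):
            aid = f"{arm}-{i + 1:02d}"
            noise = {
                lin: (np.exp(rng.normal(0.0, sigma, size=t.size)) if sigma > 0 else np.ones(t.size))
                for lin, _ in spec.baselines
            }
            for j, day in enumerate(t):
                row = {"animal_id": aid, "group": arm, "day": float(day)}
                for lin, _ in spec.baselines:
                    row[col[lin]] = round(float(curves[lin][j] * noise[lin][j]), 4)
                rows.append(row)
    truth = {
        "dips": {arm: {lin: list(d) for lin, d in dips} for arm, dips in spec.dips},
        "baselines": dict(spec.baselines),
        "seed": spec.seed,
    }
    return pd.DataFrame(rows), truth
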