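"""Monte-Carlo recovery experiments over the synthetic generators.

These are the package's calibration studies: simulate under known ground
truth, run the full analysis path, and measure how well the programmed
quantity is recovered. Used by the test suite, the analysis drivers and the
acceptance script alike.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .combination import combination_index
from .dose_response import DoseResponseCurve, fit_4pl, fit_median_effect, normalize_viability
from .efficacy import EfficacyStudy, bliss_call, bliss_expected, tc_ratio
from .io import curves_from_plates
from .simulate import (
    Agent4PL,
    ArmSpec,
    PlateSimSpec,
    XenoSimSpec,
    gen_viability_plates,
    gen_xenograft_study,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class Ic50Recovery:
    n_runs: int
    within_tolerance: int
    rel_errors: np.ndarray

    @property
    def rate(self) -> float:
        return self.within_tolerance / self.n_runs


def ic50_recovery(
    n_runs: int = 200,
    noise_sd: float = 0.05,
    replicates: int = 3,
    tolerance: float = 0.10,
    seed: int = 0,
    agent: Agent4PL = Agent4PL("HER2-TTC", 3.0, hill=2.0, unit="kBq/mL"),
) -> Ic50Recovery:
    """Fraction of noisy single-agent plates whose fitted absolute IC50 lands
    within ``tolerance`` (relative) of the programmed value.

    Each run simulates a 16-point titration (0.01-50 kBq/mL, 16 control and
    16 blank wells - a standard 384-well layout) of a steep radioconjugate
    curve centred in the tested range, with additive viability noise and
    ``replicates`` wells per concentration, then refits with the 4PL. The
    default curve uses the sensitive line's potency (IC50 3 kBq/mL) so the
    titration brackets both plateaus; a hill-1 curve can be passed instead,
    at the cost of roughly doubled IC50 variance (the 50%-of-control
    crossing flattens as the slope falls).
    """
    errors = []
    hits = 0
    for s in _child_seeds(seed, n_runs):
        spec = PlateSimSpec(
            agent_a=agent, noise_sd=noise_sd, replicates=replicates, weights=(),
            n_points=16, n_controls=16, n_blanks=16, seed=s,
        )
        df, truth = gen_viability_plates(spec)
        solo = df[(df["agent_a_conc"] > 0) & df["mixture_weight_a"].isna()]
        controls = df[df["is_control"]]["raw_signal"]
        blanks = df[df["is_blank"]]["raw_signal"]
        v = normalize_viability(solo["raw_signal"], controls, blanks)
        fit = fit_4pl(DoseResponseCurve("A", solo["agent_a_conc"].to_numpy(), v))
        if fit.absolute_ic50 is None:
            errors.append(np.inf)
            continue
        rel = abs(fit.absolute_ic50 - truth["agent_a"]["ec50"]) / truth["agent_a"]["ec50"]
        errors.append(rel)
        hits += rel <= tolerance
    return Ic50Recovery(n_runs, hits, np.asarray(errors))


@dataclass
class XenograftMC:
    n_reps: int
    target_tc: float
    mean_recovered_tc: float
    bliss_calls: dict[str, int]
    psi: float

    @property
    def call_rate(self) -> dict[str, float]:
        return {k: v / self.n_reps for k, v in self.bliss_calls.items()}


def _mc_arms(psi: float, n: int) -> tuple[ArmSpec, ...]:
    return (
        ArmSpec("vehicle", n=n),
        ArmSpec("ttc-300", ttc_kbq_kg=300.0, n=n),
        ArmSpec("ola-50", olaparib_mg_kg=50.0, n=n),
        ArmSpec("ttc-300+ola-50", 300.0, 50.0, psi=psi, n=n),
    )


def xenograft_mc(
    n_reps: int = 200,
    n_per_arm: int = 5,
    psi: float = 1.0,
    margin: float = 0.10,
    reference_day: float = 21.0,
    seed: int = 0,
) -> XenograftMC:
    """Repeatedly simulate a four-arm study and tally the Bliss calls.

    The monotherapy arms use the default calibration (300 kBq/kg and
    50 mg/kg each give model-true T/C = 0.5 at day 21); ψ multiplies the
    combination arm's kill. ψ = 1 programs exact Bliss additivity
    (combination true T/C = product of the monotherapy T/Cs), so the
    expected verdict is "additive"; a larger ψ programs synergy.

    Also records the mean recovered T/C of the tuned monotherapy arm
    (programmed 0.5 at day 21).
    """
    days = tuple(d for d in (0, 3, 7, 10, 14, 17, 21) )
    calls = {"synergistic": 0, "additive": 0, "antagonistic": 0}
    recovered = []
    base = XenoSimSpec(days=days)
    target_tc = base.true_tc(ArmSpec("ttc-300", ttc_kbq_kg=300.0), reference_day)
    for s in _child_seeds(seed, n_reps):
        spec = dataclasses.replace(base, arms=_mc_arms(psi, n_per_arm), seed=s)
        df, _, _ = gen_xenograft_study(spec)
        study = EfficacyStudy(df)
        a = tc_ratio(study, "ttc-300", reference_day, with_significance=False).t_over_c
        b = tc_ratio(study, "ola-50", reference_day, with_significance=False).t_over_c
        obs = tc_ratio(study, "ttc-300+ola-50", reference_day, with_significance=False).t_over_c
        expected = bliss_expected(min(a, 1.0), min(b, 1.0))
        calls[bliss_call(expected, obs, margin).call] += 1
        recovered.append(a)
    return XenograftMC(n_reps, target_tc, float(np.mean(recovered)), calls, psi)


def psi_for_combination_tc(target_tc: float, reference_day: float = 21.0) -> float:
    """Interaction multiplier ψ making the default 300 kBq/kg + 50 mg/kg
    combination arm reach a chosen model-true T/C at the reference day."""
    base = XenoSimSpec()
    additive = base.true_tc(ArmSpec("c", 300.0, 50.0, psi=1.0), reference_day)
    return math.log(target_tc) / math.log(additive)


def plate_ci_experiment(
    gamma: float,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    agent_a: Agent4PL = Agent4PL("A", 10.0),
    agent_b: Agent4PL = Agent4PL("B", 1.0),
    top_a: float = 50.0,
    top_b: float = 5.0,
):
    """Simulate one fixed-ratio plate and run the full CI analysis.

    Returns (spec, CombinationIndexResult).
    """
    spec = PlateSimSpec(
        agent_a=agent_a, agent_b=agent_b, top_a=top_a, top_b=top_b,
        gamma=gamma, noise_sd=noise_sd, replicates=replicates, seed=seed,
    )
    df, _ = gen_viability_plates(spec)
    ca, cb, design, mixes = curves_from_plates(df)
    res = combination_index(design, fit_median_effect(ca), fit_median_effect(cb), mixes)
    return spec, res


def brute_force_ci(spec: PlateSimSpec, weight_a: float, n_grid: int = 10_000) -> float:
    """Independent oracle: grid-search the noise-free simulated surface for
    the 50%-survival combined fraction and score it against the true single
    agent IC50s. Shares no code path with the fitting pipeline."""
    f = np.geomspace(1e-6, 1.0, n_grid)
    s = spec.mixture_survival(f, weight_a)
    f50 = float(np.interp(0.5, s[::-1], f[::-1]))
    return (
        weight_a * f50 * spec.top_a / spec.agent_a.ec50
        + (1.0 - weight_a) * f50 * spec.top_b / spec.agent_b.ec50
    )
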