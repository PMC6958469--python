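"""Radionuclide constants and decay arithmetic.

Everything here is closed-form: exponential decay/decay-correction, the
two-member Bateman equation for daughter ingrowth, specific activity, and
the activity -> molar concentration conversion used to express radiometric
IC50s (kBq/mL) in pM of nuclide.

Internal time unit is hours; half-lives are stored with their native unit
and converted once on access.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import N_A

_HOURS_PER_UNIT = {"s": 1.0 / 3600.0, "min": 1.0 / 60.0, "h": 1.0, "d": 24.0}

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide, defined by its half-life.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"Th-227"``.
    half_life : float
        Physical half-life, strictly positive.
    unit : str
        Time unit of ``half_life``: one of ``s``, ``min``, ``h``, ``d``.
    """

    name: str
    half_life: float
    unit: str = "d"

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError(f"half-life must be positive, got {self.half_life}")
        if self.unit not in _HOURS_PER_UNIT:
            raise ValueError(f"unknown time unit {self.unit!r}")

    @property
    def half_life_h(self) -> float:
        return self.half_life * _HOURS_PER_UNIT[self.unit]

    @property
    def half_life_s(self) -> float:
        return self.half_life_h * 3600.0

    @property
    def decay_constant_per_h(self) -> float:
        """λ = ln 2 / T½, in 1/h."""
        return LN2 / self.half_life_h

    @property
    def decay_constant_per_s(self) -> float:
        return LN2 / self.half_life_s


#: Alpha-emitter carried by the antibody conjugate.
TH227 = Nuclide("Th-227", 18.7, "d")
#: First daughter of Th-227; half-life from standard nuclide data.
RA223 = Nuclide("Ra-223", 11.43, "d")

REGISTRY: dict[str, Nuclide] = {"Th-227": TH227, "Ra-223": RA223}


def get_nuclide(name: str, overrides: dict[str, float] | None = None) -> Nuclide:
    """Look up a registry nuclide, optionally overriding its half-life (days)."""
    if overrides and name in overrides:
        return Nuclide(name, float(overrides[name]), "d")
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown nuclide {name!r}; registry has {sorted(REGISTRY)}") from None


def forward_decay(activity: float, elapsed_h: float, nuclide: Nuclide) -> float:
    """Activity remaining after ``elapsed_h`` hours of decay."""
    if elapsed_h < 0:
        raise ValueError("elapsed time must be non-negative")
    return activity * 2.0 ** (-elapsed_h / nuclide.half_life_h)


def decay_correct(activity: float, elapsed_h: float, nuclide: Nuclide) -> float:
    """Correct a measured activity back to a reference time ``elapsed_h`` earlier.

    Exact inverse of :func:`forward_decay`: returns ``activity * 2**(t/T½)``.
    Used to express organ counts at harvest as activity at injection time.
    """
    if elapsed_h < 0:
        raise ValueError("elapsed time must be non-negative")
    return activity * 2.0 ** (elapsed_h / nuclide.half_life_h)


def specific_activity(activity_kbq_per_kg: float, protein_mg_per_kg: float) -> float:
    """Specific activity of a radiolabeled protein dose, in kBq/µg.

    Both arguments are per-kg-body-weight dose levels, so the body weight
    cancels: 300 kBq/kg at 0.14 mg/kg antibody is 2.14 kBq/µg.
    """
    if protein_mg_per_kg <= 0:
        raise ValueError("protein dose must be positive")
    return activity_kbq_per_kg / (protein_mg_per_kg * 1000.0)


def activity_to_molar(activity_bq_per_l: float, nuclide: Nuclide) -> float:
    """Convert an activity concentration (Bq/L) to molar concentration (mol/L).

    N = A/λ atoms per litre, divided by Avogadro's number. Linear in activity
    and in half-life.
    """
    if activity_bq_per_l < 0:
        raise ValueError("activity must be non-negative")
    atoms_per_l = activity_bq_per_l / nuclide.decay_constant_per_s
    return atoms_per_l / N_A


def atoms_per_bq(nuclide: Nuclide) -> float:
    """Number of atoms sustaining 1 Bq of the given nuclide (= 1/λ in seconds)."""
    return 1.0 / nuclide.decay_constant_per_s


def bateman_ingrowth(
    parent_activity_t0: float,
    elapsed_h: float,
    parent: Nuclide = TH227,
    daughter: Nuclide = RA223,
) -> float:
    """Daughter activity grown in from a pure parent source.

    Assumes no daughter present at t = 0 and no loss of daughter from the
    sample (the no-recoil upper bound):

        A_d(t) = A_p(0) · λ_d/(λ_d − λ_p) · (exp(−λ_p t) − exp(−λ_d t))

    A dedicated limiting form λ t exp(−λ t) is used when the two decay
    constants are numerically indistinguishable.
    """
    if elapsed_h < 0:
        raise ValueError("elapsed time must be non-negative")
    lp = parent.decay_constant_per_h
    ld = daughter.decay_constant_per_h
    if math.isclose(lp, ld, rel_tol=1e-9):
        return parent_activity_t0 * lp * elapsed_h * math.exp(-lp * elapsed_h)
    return (
        parent_activity_t0
        * ld
        / (ld - lp)
        * (math.exp(-lp * elapsed_h) - math.exp(-ld * elapsed_h))
    )


def transient_equilibrium_ratio(parent: Nuclide = TH227, daughter: Nuclide = RA223) -> float:
    """Asymptotic daughter/parent activity ratio λ_d/(λ_d − λ_p).

    Requires the daughter to decay faster than the parent (transient
    equilibrium); ≈2.57 for Th-227 -> Ra-223.
    """
    lp = parent.decay_constant_per_h
    ld = daughter.decay_constant_per_h
    if ld <= lp:
        raise ValueError("transient equilibrium requires the daughter to be shorter-lived")
    return ld / (ld - lp)


def ingrowth_peak_time_h(parent: Nuclide = TH227, daughter: Nuclide = RA223) -> float:
    """Time of maximum daughter activity: ln(λ_d/λ_p)/(λ_d − λ_p)."""
    lp = parent.decay_constant_per_h
    ld = daughter.decay_constant_per_h
    if math.isclose(lp, ld, rel_tol=1e-9):
        return 1.0 / lp
    return math.log(ld / lp) / (ld - lp)
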