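"""Tumor growth metrics, T/C with significance, and Bliss synergy calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radiosynergy.efficacy import (
    INHIBITION_SCALE,
    TC_LITERAL,
    EfficacyStudy,
    anova_tukey,
    bliss_call,
    bliss_expected,
    bliss_table,
    doubling_time,
    group_doubling_time,
    tc_ratio,
)
from radiosynergy.experiments import xenograft_mc
from radiosynergy.io import load_reported_tc_table
from radiosynergy.simulate import ArmSpec, XenoSimSpec, gen_xenograft_study


def _study(frames: dict[str, np.ndarray], days) -> EfficacyStudy:
    rows = []
    for group, volumes in frames.items():
        for i, animal_volumes in enumerate(np.atleast_2d(volumes)):
            for d, v in zip(days, animal_volumes):
                rows.append(
                    {"animal_id": f"{group}{i}", "group": group, "day": d,
                     "volume_mm3": v, "body_weight_g": 25.0}
                )
    return EfficacyStudy(pd.DataFrame(rows))


class TestDoublingTime:
    def test_exact_exponential(self):
        t = np.array([0, 7, 14, 21], float)
        td, status = doubling_time(t, 90.0 * 2.0 ** (t / 7.3))
        assert status == "ok"
        np.testing.assert_allclose(td, 7.3, rtol=1e-12)

    def test_constant_series_has_no_growth(self):
        td, status = doubling_time([0, 7, 14], [100.0, 100.0, 100.0])
        assert td is None and status == "no growth"

    def test_requires_three_positive_points(self):
        with pytest.raises(ValueError):
            doubling_time([0, 7], [10.0, 20.0])

    def test_recovered_from_noisy_vehicle_arm(self):
        spec = XenoSimSpec(arms=(ArmSpec("vehicle", n=10),), noise_sd=0.1, seed=11)
        df, _, _ = gen_xenograft_study(spec)
        td, n = group_doubling_time(EfficacyStudy(df), "vehicle")
        assert n == 10
        assert abs(td - 8.3) / 8.3 < 0.15


class TestTcRatio:
    def test_identical_groups_give_one(self):
        days = [0, 7, 14]
        v = np.array([[100, 200, 400], [120, 240, 480]], float)
        study = _study({"vehicle": v, "arm": v}, days)
        r = tc_ratio(study, "arm", 14, with_significance=False)
        assert r.t_over_c == 1.0

    def test_simple_arithmetic(self):
        study = _study({"vehicle": np.array([[1500.0]]), "arm": np.array([[150.0]])}, [0])
        # endpoint censoring would drop the vehicle animal after day 0 only
        r = tc_ratio(study, "arm", 0, with_significance=False)
        np.testing.assert_allclose(r.t_over_c, 0.1)

    def test_monte_carlo_recovery_of_programmed_ratio(self):
        mc = xenograft_mc(n_reps=50, seed=3)
        assert abs(mc.mean_recovered_tc - mc.target_tc) < 0.05

    def test_reference_day_past_vehicle_censoring_rejected(self):
        days = [0, 7]
        study = _study({"vehicle": np.array([[1500.0, 1600.0]]), "arm": np.array([[90.0, 95.0]])},
                       days)
        # the vehicle animal hits the endpoint at day 0: its day-0 measurement
        # is kept, so day 0 is the only usable reference day
        assert study.default_reference_day() == 0
        with pytest.raises(ValueError, match="earlier"):
            tc_ratio(study, "arm", 7, with_significance=False)


class TestCensoring:
    def test_animal_excluded_after_endpoint(self):
        days = [0, 7, 14]
        study = _study(
            {"vehicle": np.array([[100, 1600, 3000], [100, 200, 400]], float)}, days
        )
        at14 = study.uncensored_at(14)
        assert set(at14["animal_id"]) == {"vehicle1"}
        at7 = study.uncensored_at(7)  # the triggering measurement itself is kept
        assert set(at7["animal_id"]) == {"vehicle0", "vehicle1"}


class TestAnovaTukey:
    def test_null_case_not_significant(self, rng):
        v = rng.normal(500, 50, size=(2, 10))
        study = _study({"vehicle": np.tile(v[0][:, None], 1), "arm": np.tile(v[1][:, None], 1)},
                       [0])
        p = anova_tukey(study, 0)["arm"]
        assert p > 0.05

    def test_separated_groups_highly_significant(self, rng):
        study = _study(
            {"vehicle": rng.normal(1000, 1, (10, 1)), "arm": rng.normal(100, 1, (10, 1))}, [0]
        )
        assert anova_tukey(study, 0)["arm"] < 1e-6

    def test_agrees_with_permutation_oracle_ordering(self, rng):
        """Three small groups: Tukey p-values rank the vehicle contrasts the
        same way as an exhaustive permutation test on the same data."""
        veh = rng.normal(500, 60, 4)
        mid = rng.normal(460, 60, 4)
        strong = rng.normal(250, 60, 4)
        study = _study(
            {"vehicle": veh[:, None], "mid": mid[:, None], "strong": strong[:, None]}, [0]
        )
        tukey = anova_tukey(study, 0)

        def perm_p(a, b):
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            count = total = 0
            for idx in itertools.combinations(range(8), 4):
                sel = np.zeros(8, bool)
                sel[list(idx)] = True
                diff = abs(pooled[sel].mean() - pooled[~sel].mean())
                count += diff >= obs - 1e-12
                total += 1
            return count / total

        oracle = {"mid": perm_p(veh, mid), "strong": perm_p(veh, strong)}
        assert (tukey["strong"] < tukey["mid"]) == (oracle["strong"] < oracle["mid"])

    def test_degenerate_variance_rejected(self):
        study = _study({"vehicle": np.full((3, 1), 100.0), "arm": np.full((3, 1), 100.0)}, [0])
        with pytest.raises(ValueError, match="degenerate"):
            anova_tukey(study, 0)


class TestBlissExpected:
    def test_literal_formula_on_tc(self):
        assert bliss_expected(0.5, 0.5, TC_LITERAL) == 0.75

    def test_inhibition_scale_on_printed_monotherapy_pair(self):
        np.testing.assert_allclose(bliss_expected(0.8, 0.5), 0.40)

    def test_boundary_identity_at_zero(self):
        assert bliss_expected(0.0, 0.7) == 0.0
        assert bliss_expected(0.0, 0.7, TC_LITERAL) == 0.7

    def test_tc_above_one_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert bliss_expected(1.2, 0.5) == 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bliss_expected(1.6, 0.5)

    @settings(derandomize=True, max_examples=300)
    @given(a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0))
    def test_conventions_are_complements(self, a, b):
        """1 - literal(1-A, 1-B) = A*B: the printed formula on the inhibition
        scale is exactly the survival-scale product."""
        lhs = 1.0 - bliss_expected(1.0 - a, 1.0 - b, TC_LITERAL)
        assert abs(lhs - a * b) < 5e-16

    @settings(derandomize=True, max_examples=300)
    @given(a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0))
    def test_convention_bounds(self, a, b):
        assert bliss_expected(a, b) <= min(a, b) + 1e-15
        assert bliss_expected(a, b, TC_LITERAL) >= max(a, b) - 1e-15


class TestBlissCall:
    @pytest.mark.parametrize(
        "expected, observed, verdict",
        [
            (0.40, 0.10, "synergistic"),  # printed 125 kBq/kg + 50 mg/kg arm
            (0.50, 0.45, "additive"),
            (0.30, 0.45, "antagonistic"),
            (0.40, 0.30, "additive"),  # boundary inclusive
        ],
    )
    def test_margin_classification(self, expected, observed, verdict):
        assert bliss_call(expected, observed).call == verdict

    def test_margin_validation(self):
        with pytest.raises(ValueError):
            bliss_call(0.5, 0.5, margin=0.0)

    @settings(derandomize=True, max_examples=200)
    @given(exp=st.floats(0.0, 1.0), o1=st.floats(0.0, 1.5), o2=st.floats(0.0, 1.5))
    def test_call_is_monotone_in_observed(self, exp, o1, o2):
        """Lowering the observed T/C never moves the verdict away from synergy."""
        order = {"antagonistic": 0, "additive": 1, "synergistic": 2}
        lo, hi = min(o1, o2), max(o1, o2)
        assert order[bliss_call(exp, lo).call] >= order[bliss_call(exp, hi).call]


class TestPublishedPattern:
    def test_synergy_called_only_for_the_two_high_dose_knockout_arms(self):
        """Default pipeline on the published T/C values reproduces the reported
        synergy pattern: only 125+50 and 300+50 in the BRCA2-knockout model."""
        table = load_reported_tc_table()
        for model, sub in table.groupby("model"):
            tc = {(float(r.ttc_kbq_kg), float(r.olaparib_mg_kg)): float(r.t_over_c)
                  for r in sub.itertuples()}
            calls = bliss_table(tc)
            syn = {(r.ttc_dose, r.olaparib_dose) for r in calls.itertuples()
                   if r.call == "synergistic"}
            if model == "brca2_ko":
                assert syn == {(125.0, 50.0), (300.0, 50.0)}
                additive = {(r.ttc_dose, r.olaparib_dose) for r in calls.itertuples()
                            if r.call == "additive"}
                assert {(125.0, 25.0), (300.0, 25.0)} <= additive
            else:
                assert syn == set()

    def test_missing_monotherapy_arm_rejected(self):
        with pytest.raises(KeyError, match="monotherapy"):
            bliss_table({(100.0, 50.0): 0.2, (100.0, 0.0): 0.5})
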