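"""Decay correction, %IA/g, specific activity, molarity and Bateman ingrowth."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radiosynergy.biodist import ActivityMeasurement, biodist_table, percent_ia_per_gram, tumor_to_blood
from radiosynergy.nuclides import (
    RA223,
    TH227,
    Nuclide,
    activity_to_molar,
    atoms_per_bq,
    bateman_ingrowth,
    decay_correct,
    forward_decay,
    get_nuclide,
    ingrowth_peak_time_h,
    specific_activity,
    transient_equilibrium_ratio,
)


class TestDecay:
    def test_zero_elapsed_is_identity(self):
        assert decay_correct(123.4, 0.0, TH227) == 123.4

    def test_one_half_life_doubles(self):
        np.testing.assert_allclose(decay_correct(1.0, TH227.half_life_h, TH227), 2.0)

    def test_336h_correction_factor(self):
        np.testing.assert_allclose(decay_correct(1.0, 336.0, TH227), 2.0 ** (14.0 / 18.7))

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            decay_correct(1.0, -1.0, TH227)

    @settings(derandomize=True, max_examples=100)
    @given(t=st.floats(0.0, 5000.0), a=st.floats(1e-6, 1e9))
    def test_round_trip_inverts_forward_decay(self, t, a):
        np.testing.assert_allclose(decay_correct(forward_decay(a, t, TH227), t, TH227), a,
                                   rtol=1e-12)


class TestPercentIaPerGram:
    def test_entire_dose_in_one_gram_is_100(self):
        m = ActivityMeasurement("tumor", 0.0, 5000.0, 1.0, 5000.0)
        assert percent_ia_per_gram(m) == 100.0

    def test_half_dose_in_two_grams_is_25(self):
        m = ActivityMeasurement("tumor", 0.0, 2500.0, 2.0, 5000.0)
        assert percent_ia_per_gram(m) == 25.0

    def test_decay_correction_applied(self):
        m = ActivityMeasurement("tumor", 336.0, 500.0, 1.0, 5000.0)
        np.testing.assert_allclose(percent_ia_per_gram(m), 10.0 * 2.0 ** (14.0 / 18.7))

    def test_linear_in_activity_inverse_in_mass(self, rng):
        a, mass = rng.uniform(10, 1e4), rng.uniform(0.1, 3.0)
        base = percent_ia_per_gram(ActivityMeasurement("s", 24.0, a, mass, 1e4))
        np.testing.assert_allclose(
            percent_ia_per_gram(ActivityMeasurement("s", 24.0, 3 * a, mass, 1e4)), 3 * base
        )
        np.testing.assert_allclose(
            percent_ia_per_gram(ActivityMeasurement("s", 24.0, a, 2 * mass, 1e4)), base / 2
        )

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            ActivityMeasurement("s", 0.0, 1.0, 0.0, 1.0)


class TestTumorToBlood:
    @staticmethod
    def _frame(tumor, blood):
        return pd.DataFrame(
            {
                "group": ["g"] * 2,
                "organ": ["tumor", "blood"],
                "time_h": [336.0, 336.0],
                "percent_ia_per_g": [tumor, blood],
            }
        )

    def test_simple_ratio(self):
        assert tumor_to_blood(self._frame(10.0, 5.0), 336.0) == 2.0
        assert tumor_to_blood(self._frame(7.0, 7.0), 336.0) == 1.0

    def test_zero_blood_returns_nan(self):
        assert math.isnan(tumor_to_blood(self._frame(10.0, 0.0), 336.0))

    def test_missing_time_point_rejected(self):
        with pytest.raises(ValueError):
            tumor_to_blood(self._frame(10.0, 5.0), 24.0)


class TestSpecificActivity:
    def test_study_dose_levels(self):
        # 300 kBq/kg at 0.14 mg/kg protein: 2.1 kBq/ug to two significant figures
        assert round(specific_activity(300.0, 0.14), 1) == 2.1
        assert specific_activity(100.0, 0.1) == 1.0
        # unrounded value for the 600 kBq/kg level
        np.testing.assert_allclose(specific_activity(600.0, 0.14), 4.285714, rtol=1e-6)

    def test_zero_protein_rejected(self):
        with pytest.raises(ValueError):
            specific_activity(100.0, 0.0)


class TestActivityToMolar:
    def test_zero_activity(self):
        assert activity_to_molar(0.0, TH227) == 0.0

    def test_atoms_per_bq_th227(self):
        np.testing.assert_allclose(atoms_per_bq(TH227), 1.0 / (math.log(2) / (18.7 * 86400)),
                                   rtol=1e-12)
        assert 2.32e6 < atoms_per_bq(TH227) < 2.34e6

    def test_22_kbq_per_ml_is_about_85_pm(self):
        pm = activity_to_molar(22e3 * 1000.0, TH227) * 1e12
        np.testing.assert_allclose(pm, 85.15, rtol=1e-3)

    def test_linear_in_activity_and_half_life(self):
        base = activity_to_molar(1000.0, TH227)
        np.testing.assert_allclose(activity_to_molar(2000.0, TH227), 2 * base)
        double = Nuclide("X", 2 * 18.7, "d")
        np.testing.assert_allclose(activity_to_molar(1000.0, double), 2 * base)


class TestBateman:
    def test_no_daughter_at_time_zero(self):
        assert bateman_ingrowth(1000.0, 0.0) == 0.0

    def test_transient_equilibrium_ratio(self):
        # lambda_d/(lambda_d - lambda_p) = T_p/(T_p - T_d) for this pair
        np.testing.assert_allclose(transient_equilibrium_ratio(), 18.7 / (18.7 - 11.43),
                                   rtol=1e-12)
        np.testing.assert_allclose(transient_equilibrium_ratio(), 2.572, atol=5e-4)

    def test_ratio_converges_to_equilibrium(self):
        # the approach is 1 - exp(-(ld-lp)t): ~9.5% short at 100 d, <1% by 200 d
        t = 200.0 * 24.0
        ratio = bateman_ingrowth(1.0, t) / forward_decay(1.0, t, TH227)
        np.testing.assert_allclose(ratio, transient_equilibrium_ratio(), rtol=0.01)

    def test_peak_ingrowth_near_day_21(self):
        peak_h = ingrowth_peak_time_h()
        np.testing.assert_allclose(peak_h / 24.0, 20.88, atol=0.01)
        a_peak = bateman_ingrowth(1.0, peak_h)
        assert a_peak > bateman_ingrowth(1.0, peak_h - 24.0)
        assert a_peak > bateman_ingrowth(1.0, peak_h + 24.0)

    def test_nonnegative_unimodal_with_monotone_ratio(self):
        t = np.linspace(0.0, 200 * 24.0, 400)
        a_d = np.array([bateman_ingrowth(1.0, x) for x in t])
        assert (a_d >= 0).all()
        peaks = np.flatnonzero(np.diff(np.sign(np.diff(a_d))) < 0)
        assert len(peaks) == 1
        ratio = a_d[1:] / np.array([forward_decay(1.0, x, TH227) for x in t[1:]])
        assert (np.diff(ratio) > 0).all()

    def test_equal_decay_constant_limit(self):
        twin = Nuclide("twin", TH227.half_life, "d")
        near = Nuclide("near", TH227.half_life * (1 + 1e-7), "d")
        t = 10 * 24.0
        exact = bateman_ingrowth(1.0, t, TH227, twin)
        limit = bateman_ingrowth(1.0, t, TH227, near)
        np.testing.assert_allclose(exact, limit, rtol=1e-5)


class TestRegistry:
    def test_registry_half_lives(self):
        assert get_nuclide("Th-227").half_life == 18.7
        assert get_nuclide("Ra-223").half_life == 11.43

    def test_override_and_unknown(self):
        assert get_nuclide("Th-227", {"Th-227": 20.0}).half_life == 20.0
        with pytest.raises(KeyError):
            get_nuclide("Xx-999")

    def test_invalid_nuclide(self):
        with pytest.raises(ValueError):
            Nuclide("bad", -1.0, "d")
        with pytest.raises(ValueError):
            Nuclide("bad", 1.0, "fortnight")
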