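"""Fixed-ratio combination index: sham null, oracle agreement, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import four_pl, sham_ci
from radiosynergy.combination import (
    NINE_RATIO_WEIGHTS,
    FixedRatioDesign,
    classify_ci,
    combination_index,
    isobologram_points,
)
from radiosynergy.dose_response import DoseResponseCurve, fit_4pl, fit_median_effect
from radiosynergy.experiments import brute_force_ci, plate_ci_experiment


class TestShamNull:
    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0, 4.0])
    def test_self_combination_ci_is_one(self, hill):
        """A drug combined with itself is additive by construction: CI = 1."""
        res = sham_ci(hill)
        assert res.n_excluded == 0
        for r in res.per_ratio:
            np.testing.assert_allclose(r.ci, 1.0, atol=0.02)
        np.testing.assert_allclose(res.average_ci, 1.0, atol=0.02)
        assert res.classification == "additive"

    def test_sham_isobologram_points_on_additivity_line(self):
        res = sham_ci(1.5)
        d = np.geomspace(0.01, 50.0, 9)
        fit = fit_4pl(DoseResponseCurve("A", d, four_pl(d, 10.0, 1.5)))
        pts = isobologram_points(fit, fit, res)
        ic50 = fit.absolute_ic50
        for p in pts:
            np.testing.assert_allclose(p.dose_a / ic50 + p.dose_b / ic50, 1.0, atol=0.02)


class TestUnitInvariance:
    def test_ci_invariant_under_concentration_rescaling(self):
        """Multiplying one agent's unit by k leaves every CI unchanged."""
        spec, res = plate_ci_experiment(gamma=1.3)
        k = 137.0
        d = np.geomspace(spec.min_a, spec.top_a, spec.n_points)
        curve_a = DoseResponseCurve("A", d * k, spec.agent_a.survival(d))
        curve_b = DoseResponseCurve("B", np.geomspace(spec.min_b, spec.top_b, spec.n_points),
                                    spec.agent_b.survival(np.geomspace(spec.min_b, spec.top_b,
                                                                       spec.n_points)))
        f = np.geomspace(max(spec.min_a / spec.top_a, spec.min_b / spec.top_b), 1.0,
                         spec.n_points)
        mixes = [
            DoseResponseCurve("mix", f, spec.mixture_survival(f, wa), unit="fraction")
            for wa, _ in NINE_RATIO_WEIGHTS
        ]
        base = combination_index(
            FixedRatioDesign(spec.top_a, spec.top_b),
            fit_median_effect(DoseResponseCurve("A", d, spec.agent_a.survival(d))),
            fit_median_effect(curve_b), mixes,
        )
        scaled = combination_index(
            FixedRatioDesign(spec.top_a * k, spec.top_b),
            fit_median_effect(curve_a), fit_median_effect(curve_b), mixes,
        )
        np.testing.assert_allclose(scaled.average_ci, base.average_ci, rtol=1e-8)


class TestOracleAgreement:
    def test_bliss_independent_surface_matches_brute_force_oracle(self):
        """hill-1 agents, IC50s 10 and 1: pipeline CI vs 10^4-point grid search."""
        spec, res = plate_ci_experiment(gamma=1.0)
        for r in res.per_ratio:
            oracle = brute_force_ci(spec, r.weight_a)
            np.testing.assert_allclose(r.ci, oracle, rtol=0.02)

    def test_synergistic_surface_classified_and_below_additivity_line(self):
        spec, res = plate_ci_experiment(gamma=1.6)
        assert res.average_ci < 0.8
        assert res.classification == "synergistic"
        for r in res.per_ratio:
            oracle = brute_force_ci(spec, r.weight_a)
            np.testing.assert_allclose(r.ci, oracle, rtol=0.05)
            # interior point strictly below the Loewe additivity line
            assert r.dose_a / spec.agent_a.ec50 + r.dose_b / spec.agent_b.ec50 < 1.0

    def test_antagonistic_surface(self):
        _, res = plate_ci_experiment(gamma=0.45)
        assert res.average_ci > 1.2
        assert res.classification == "antagonistic"


class TestClassification:
    @pytest.mark.parametrize(
        "ci, expected",
        [
            (0.6, "synergistic"),
            (1.0, "additive"),
            (0.8, "additive"),  # boundaries are additive
            (1.2, "additive"),
            (0.79999, "synergistic"),
            (1.20001, "antagonistic"),
        ],
    )
    def test_thresholds(self, ci, expected):
        assert classify_ci(ci) == expected

    @settings(derandomize=True, max_examples=200)
    @given(ci=st.floats(0.0, 10.0))
    def test_classes_partition_the_ci_line(self, ci):
        assert classify_ci(ci) in {"synergistic", "additive", "antagonistic"}


class TestExclusions:
    def test_weak_mixture_flagged_and_excluded(self):
        """A mixture that never reaches 50% effect is dropped from the average."""
        d = np.geomspace(0.01, 50.0, 9)
        me = fit_median_effect(DoseResponseCurve("A", d, four_pl(d, 10.0)))
        f = np.geomspace(1e-3, 1.0, 9)
        good = DoseResponseCurve("mix", f, four_pl(f * 50.0, 10.0), unit="fraction")
        weak = DoseResponseCurve("mix", f, four_pl(f * 50.0, 1e5, 1.0, 1.0, 0.8),
                                 unit="fraction")
        design = FixedRatioDesign(50.0, 50.0, weights=((0.5, 0.5), (0.4, 0.6)))
        with pytest.warns(UserWarning, match="excluded"):
            res = combination_index(design, me, me, [good, weak])
        assert res.n_excluded == 1
        assert res.per_ratio[1].excluded
        assert "effect" in res.per_ratio[1].reason
        np.testing.assert_allclose(res.average_ci, res.per_ratio[0].ci)

    def test_isobologram_propagates_undefined_ic50(self):
        res = sham_ci(1.0)
        d = np.geomspace(0.01, 50.0, 9)
        ok = fit_4pl(DoseResponseCurve("A", d, four_pl(d, 10.0)))
        flat = fit_4pl(DoseResponseCurve("B", d, np.ones_like(d)))
        with pytest.raises(ValueError, match="undefined"):
            isobologram_points(ok, flat, res)

    def test_ratio_ci_equals_normalized_dose_sum(self):
        """A point with CI c has normalized coordinate sum c by definition."""
        spec, res = plate_ci_experiment(gamma=1.6)
        for r in res.per_ratio:
            np.testing.assert_allclose(
                r.dose_a / spec.agent_a.ec50 + r.dose_b / spec.agent_b.ec50, r.ci, rtol=1e-6
            )


def test_design_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        FixedRatioDesign(1.0, 1.0, weights=((0.5, 0.6),))
    with pytest.raises(ValueError, match="strictly inside"):
        FixedRatioDesign(1.0, 1.0, weights=((1.0, 0.0),))
    with pytest.raises(ValueError, match="positive"):
        FixedRatioDesign(0.0, 1.0)
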