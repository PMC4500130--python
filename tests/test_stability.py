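"""Stability-confidence inversion, curves, classification and binning."""

import math

import numpy as np
import pytest

from thermokin.arrhenius import ArrheniusFit, fit_arrhenius
from thermokin.kinetics import rate_from_halflife
from thermokin.stability import (
    DEFAULT_P_GRID,
    DEFAULT_TARGETS,
    ConfidenceCurve,
    StabilityAssessment,
    StabilityClassifier,
    classify_stability,
    confidence_rate_below,
    default_temperature_grid,
    grid_search_confidence,
    histogram_t50,
    stability_curve,
    temperature_at_confidence,
)

from .conftest import arrhenius_lnk, measurements_from_lnk, random_fits


def crossing_temperature(fit, k_target):
    """T where the fitted line equals ln k_target (closed form)."""
    return fit.gradient_b / (math.log(k_target) - fit.intercept_a)


class TestConfidenceRateBelow:
    def test_half_at_the_fitted_line(self, noisy_fit):
        k_target = rate_from_halflife(60.0)
        t_star = crossing_temperature(noisy_fit, k_target)
        assert confidence_rate_below(noisy_fit, t_star, k_target) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_monotone_nonincreasing_in_temperature(self, noisy_fit):
        k_target = rate_from_halflife(60.0)
        grid = default_temperature_grid()
        conf = [confidence_rate_below(noisy_fit, float(t), k_target) for t in grid]
        assert all(a >= b - 1e-12 for a, b in zip(conf, conf[1:]))

    def test_degenerate_fit_is_a_step(self, exact_fit):
        k_target = rate_from_halflife(60.0)
        t_star = crossing_temperature(exact_fit, k_target)
        assert confidence_rate_below(exact_fit, t_star - 5.0, k_target) == 1.0
        assert confidence_rate_below(exact_fit, t_star + 5.0, k_target) == 0.0

    def test_nonpositive_target_rejected(self, noisy_fit):
        with pytest.raises(ValueError):
            confidence_rate_below(noisy_fit, 400.0, 0.0)


class TestGridSearchOracle:
    def test_matches_closed_form_within_grid_resolution(self):
        k_target = rate_from_halflife(60.0)
        temps = np.linspace(300.0, 640.0, 35)
        for fit in random_fits(10, seed=23):
            for t in temps:
                closed = confidence_rate_below(fit, float(t), k_target)
                gridded = grid_search_confidence(fit, float(t), k_target)
                assert abs(closed - gridded) <= 0.005

    def test_symmetric_case_is_half(self, noisy_fit):
        k_target = rate_from_halflife(60.0)
        t_star = crossing_temperature(noisy_fit, k_target)
        got = grid_search_confidence(noisy_fit, t_star, k_target)
        assert got == pytest.approx(0.5, abs=DEFAULT_P_GRID[0] / 2 + 1e-12)

    def test_degenerate_fit_convention(self, exact_fit):
        k_target = rate_from_halflife(60.0)
        t_star = crossing_temperature(exact_fit, k_target)
        assert grid_search_confidence(exact_fit, t_star - 5.0, k_target) == 1.0
        assert grid_search_confidence(exact_fit, t_star + 5.0, k_target) == 0.0

    def test_empty_grid_rejected(self, noisy_fit):
        with pytest.raises(ValueError):
            grid_search_confidence(noisy_fit, 400.0, 0.01, p_grid=np.array([]))


class TestStabilityCurve:
    def test_step_shape_for_exact_fit(self, exact_fit):
        curve = stability_curve(exact_fit, 60.0, metabolite_id="m")
        vals = set(np.unique(curve.confidences))
        assert vals <= {0.0, 0.5, 1.0}
        assert curve.confidences[0] == 1.0 and curve.confidences[-1] == 0.0

    def test_monotone_for_negative_gradient(self):
        for fit in random_fits(6, seed=31):
            curve = stability_curve(fit, 600.0, metabolite_id="m")
            assert curve.is_monotone_nonincreasing()

    def test_doubling_halflife_lowers_the_crossing(self, noisy_fit):
        c1 = stability_curve(noisy_fit, 60.0, metabolite_id="m")
        c2 = stability_curve(noisy_fit, 120.0, metabolite_id="m")
        t1, _ = temperature_at_confidence(c1, 0.5)
        t2, _ = temperature_at_confidence(c2, 0.5)
        assert t2 < t1

    def test_extrapolation_flags_follow_fitted_range(self, noisy_fit):
        curve = stability_curve(noisy_fit, 60.0, metabolite_id="m")
        lo, hi = noisy_fit.temperature_range
        inside = (curve.temperatures >= lo) & (curve.temperatures <= hi)
        assert not curve.extrapolated[inside].any()
        assert curve.extrapolated[~inside].all()

    def test_grid_outside_window_rejected(self, noisy_fit):
        with pytest.raises(ValueError):
            stability_curve(noisy_fit, 60.0, grid=np.array([200.0, 400.0]))


class TestTemperatureAtConfidence:
    def test_exact_grid_point_crossing(self):
        curve = ConfidenceCurve(
            "m", 60.0,
            np.array([300.0, 310.0, 320.0]),
            np.array([1.0, 0.5, 0.0]),
            np.zeros(3, dtype=bool),
        )
        t, reason = temperature_at_confidence(curve, 0.5)
        assert t == 310.0 and reason is None

    def test_linear_interpolation(self):
        curve = ConfidenceCurve(
            "m", 60.0,
            np.array([300.0, 310.0]),
            np.array([0.8, 0.2]),
            np.zeros(2, dtype=bool),
        )
        t, _ = temperature_at_confidence(curve, 0.5)
        assert t == pytest.approx(305.0)

    def test_never_crossing_returns_reason(self):
        flat = ConfidenceCurve(
            "m", 60.0,
            np.array([300.0, 400.0, 500.0]),
            np.array([0.9, 0.85, 0.8]),
            np.zeros(3, dtype=bool),
        )
        t, reason = temperature_at_confidence(flat, 0.5)
        assert t is None and reason == "never_crosses_in_window"
        low = ConfidenceCurve(
            "m", 60.0,
            np.array([300.0, 400.0]),
            np.array([0.3, 0.1]),
            np.zeros(2, dtype=bool),
        )
        t, reason = temperature_at_confidence(low, 0.5)
        assert t is None and reason == "below_level_at_window_start"

    def test_agrees_with_bisection_oracle(self, noisy_fit):
        k_target = rate_from_halflife(60.0)
        curve = stability_curve(noisy_fit, 60.0, metabolite_id="m")
        t_grid, _ = temperature_at_confidence(curve, 0.5)
        lo, hi = 300.0, 640.0
        for _ in range(60):  # bisection on the closed form
            mid = (lo + hi) / 2
            if confidence_rate_below(noisy_fit, mid, k_target) >= 0.5:
                lo = mid
            else:
                hi = mid
        assert abs(t_grid - (lo + hi) / 2) < 0.5

    def test_exact_fit_crossing_matches_analytic(self, exact_fit):
        curve = stability_curve(exact_fit, 60.0, metabolite_id="m")
        t_grid, _ = temperature_at_confidence(curve, 0.5)
        t_true = crossing_temperature(exact_fit, rate_from_halflife(60.0))
        assert abs(t_grid - t_true) <= 1.0  # grid resolution


def _curve_from_confidences(conf, metabolite="m", target=600.0):
    temps = np.linspace(300.0, 640.0, len(conf))
    return ConfidenceCurve(
        metabolite, target, temps, np.asarray(conf, dtype=float),
        np.zeros(len(conf), dtype=bool),
    )


class TestClassification:
    def test_sharp_curve_failing_at_ref_is_labile(self, exact_fit):
        # exact fit crosses ~415 K for the 600 s target: 0 confidence at 420 K
        long_curve = stability_curve(exact_fit, 600.0, metabolite_id="m")
        short_curve = stability_curve(exact_fit, 60.0, metabolite_id="m")
        a = classify_stability(long_curve, short_curve)
        assert a.call == "labile"
        assert a.short_vulnerable == (a.conf_at_ref_short < 0.95)

    def test_flat_curve_is_uncertain(self):
        n = 341
        conf = np.full(n, 0.55) - 0.1 * np.linspace(0, 1, n)  # 0.55 -> 0.45
        a = classify_stability(
            _curve_from_confidences(conf), _curve_from_confidences(conf, target=60.0)
        )
        assert a.call == "uncertain"

    def test_high_confidence_at_ref_is_stable(self):
        conf = np.linspace(0.999, 0.96, 341)
        a = classify_stability(
            _curve_from_confidences(conf), _curve_from_confidences(conf, target=60.0)
        )
        assert a.call == "stable"

    def test_mismatched_metabolites_rejected(self):
        c1 = _curve_from_confidences(np.linspace(1, 0, 11), metabolite="a")
        c2 = _curve_from_confidences(np.linspace(1, 0, 11), metabolite="b")
        with pytest.raises(ValueError):
            classify_stability(c1, c2)

    def test_stable_at_ref_also_stable_at_lower_ref(self):
        # monotone curve: stability at 420 K implies stability below it
        conf = np.clip(np.linspace(1.2, -0.2, 341), 0.0, 1.0)
        c = _curve_from_confidences(conf)
        cs = _curve_from_confidences(conf, target=60.0)
        base = StabilityClassifier(ref_temperature=420.0).assess(c, cs)
        if base.call == "stable":
            for ref in (410.0, 380.0, 330.0):
                assert StabilityClassifier(ref_temperature=ref).assess(c, cs).call == "stable"

    def test_steepness_span_separates_labile_from_uncertain(self):
        temps = np.linspace(300.0, 640.0, 341)
        # logistic curves centred at 400 K with controlled 0.9->0.1 spans
        for width, expected in ((10.0, "labile"), (60.0, "uncertain")):
            conf = 1.0 / (1.0 + np.exp((temps - 400.0) / width))
            c = _curve_from_confidences(conf)
            cs = _curve_from_confidences(conf, target=60.0)
            span = 2 * width * math.log(9.0)  # analytic 0.9 -> 0.1 distance
            a = classify_stability(c, cs, steepness_span=100.0)
            assert (span <= 100.0) == (a.call == "labile"), (width, span)
            assert a.call == expected


class TestHistogram:
    def _assessment(self, t50_long, t50_short, met="m"):
        return StabilityAssessment(
            metabolite_id=met, class_code="S", t50_long=t50_long, t50_short=t50_short,
            conf_at_ref_long=0.5, conf_at_ref_short=0.5, call="uncertain",
            short_vulnerable=False,
        )

    def test_bin_edges_are_lower_inclusive(self):
        df, absent = histogram_t50([self._assessment(309.9, 310.0)])
        row300 = df[df.bin_lower_K == 300.0].iloc[0]
        row310 = df[df.bin_lower_K == 310.0].iloc[0]
        assert row300.count_long == 1 and row300.count_short == 0
        assert row310.count_short == 1
        assert absent == {"long": 0, "short": 0}

    def test_empty_input(self):
        df, absent = histogram_t50([])
        assert df.empty
        assert absent == {"long": 0, "short": 0}

    def test_counts_match_hand_binning(self):
        t50s = [(305.0, 411.0), (307.5, 415.0), (423.0, None), (429.9, 511.0), (None, 519.0)]
        df, absent = histogram_t50([self._assessment(a, b) for a, b in t50s])
        by_bin = {r.bin_lower_K: (r.count_long, r.count_short) for r in df.itertuples()}
        assert by_bin[300.0] == (2, 0)
        assert by_bin[410.0] == (0, 2)
        assert by_bin[420.0] == (2, 0)
        assert by_bin[510.0] == (0, 2)
        assert absent == {"long": 1, "short": 1}
        assert df.count_long.sum() == 4 and df.count_short.sum() == 4

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            histogram_t50([], bin_width=0.0)


class TestTargetsRegistry:
    def test_registry_covers_all_class_codes(self):
        assert set(DEFAULT_TARGETS) == set("ASDLNGTIEC")

    def test_sugar_short_target_is_the_sixty_second_threshold(self):
        assert DEFAULT_TARGETS["S"].short_halflife == 60.0
        assert DEFAULT_TARGETS["D"] == DEFAULT_TARGETS["S"].__class__(
            "D", 600.0, 60.0
        )

    def test_lipids_row_shipped_as_published(self):
        # long < short for lipids, inverted vs every other class; kept as-is
        lip = DEFAULT_TARGETS["L"]
        assert (lip.long_halflife, lip.short_halflife) == (500.0, 5000.0)
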