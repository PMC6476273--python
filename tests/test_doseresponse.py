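"""Unit and property tests for the 4PL machinery and curve metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrtune.curves import ResponseCurve
from gpcrtune.doseresponse import (
    FourPL,
    GrowthSeries,
    MixtureSpec,
    UnfittableError,
    compose_mixture,
    curve_metrics,
    fit_fourpl,
    fourpl_eval,
    growth_rate,
    r_squared,
    span_fold_change,
)


class TestFourPLEval:
    @pytest.mark.parametrize(
        "p, x, expected",
        [
            (FourPL(0.0, 1.0, 1e-7, 1.0), 1e-7, 0.5),  # inflection midpoint
            (FourPL(0.0, 2.0, 1e-7, 1.0), 1e-7, 0.5),
            (FourPL(2.0, 1.5, 1e-8, 10.0), 1e-8, 6.0),  # (A+D)/2 at x=C
            (FourPL(0.0, 1.0, 1e-7, 1.0), 0.0, 0.0),  # x=0 returns A for B>0
            (FourPL(5.0, 1.0, 1e-7, 1.0), 0.0, 5.0),
        ],
    )
    def test_fixed_points(self, p, x, expected):
        assert fourpl_eval(p, x) == pytest.approx(expected, rel=1e-12)

    def test_saturates_to_maximum_asymptote(self):
        p = FourPL(0.0, 1.0, 1e-7, 1.0)
        assert fourpl_eval(p, 1e3) == pytest.approx(1.0, rel=1e-9)

    def test_monotone_in_dose_for_activating_curve(self, example_fourpl):
        x = np.logspace(-12, -4, 200)
        y = fourpl_eval(example_fourpl, x)
        assert np.all(np.diff(y) > 0)

    def test_rejects_negative_dose(self, example_fourpl):
        with pytest.raises(ValueError):
            fourpl_eval(example_fourpl, -1.0)


class TestFitFourPL:
    def test_noise_free_round_trip_recovers_truth(self, example_fourpl):
        doses = np.concatenate([[0.0], np.logspace(-10, -5, 12)])
        curve = ResponseCurve(doses, fourpl_eval(example_fourpl, doses))
        fit, report = fit_fourpl(curve)
        for name in "ABCD":
            assert getattr(fit, name) == pytest.approx(
                getattr(example_fourpl, name), rel=1e-6
            )
        assert report.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_data_is_unfittable(self):
        doses = np.logspace(-9, -5, 8)
        with pytest.raises(UnfittableError):
            fit_fourpl(ResponseCurve(doses, np.full(8, 3.0)))

    def test_too_few_distinct_doses_rejected(self):
        doses = np.logspace(-9, -7, 4)
        with pytest.raises(ValueError):
            fit_fourpl(ResponseCurve(doses, np.array([1.0, 2.0, 3.0, 4.0])))

    def test_replicate_points_accepted_as_raw_pairs(self, example_fourpl):
        doses = np.tile(np.logspace(-10, -5, 10), 3)
        resp = fourpl_eval(example_fourpl, doses)
        fit, _ = fit_fourpl((doses, resp))
        assert fit.C == pytest.approx(example_fourpl.C, rel=1e-6)


class TestCurveMetrics:
    def test_operational_range_closed_form(self):
        # at B = 1 the 5%-95% span is 2*log10(19) orders
        m = curve_metrics(FourPL(0.0, 1.0, 1e-7, 1.0), basal_floor=0.01)
        assert m.operational_range_orders == pytest.approx(
            2 * math.log10(19.0), abs=1e-12
        )

    def test_operational_range_halves_when_slope_doubles(self):
        m1 = curve_metrics(FourPL(0.0, 1.0, 1e-7, 1.0), basal_floor=0.01)
        m2 = curve_metrics(FourPL(0.0, 2.0, 1e-7, 1.0), basal_floor=0.01)
        assert m2.operational_range_orders == pytest.approx(
            m1.operational_range_orders / 2, rel=1e-12
        )

    @pytest.mark.parametrize("b", [0.2, 0.5, 1.0, 1.7, 4.0, 10.0])
    def test_span_matches_numeric_inversion(self, b):
        p = FourPL(0.0, b, 1e-7, 1.0)
        m = curve_metrics(p, basal_floor=0.01)
        x05 = p.C * (0.05 / 0.95) ** (1.0 / b)
        x95 = p.C * (0.95 / 0.05) ** (1.0 / b)
        assert m.operational_range_orders == pytest.approx(
            math.log10(x95 / x05), abs=1e-9
        )

    def test_tightness_and_dynamic_range_definitions(self):
        m = curve_metrics(FourPL(1.0, 1.0, 1e-7, 100.0))
        assert m.dynamic_range == pytest.approx(100.0)
        assert m.tightness == pytest.approx(1.0)

    def test_sensitivity_is_dose_of_twofold_change(self):
        p = FourPL(1.0, 1.3, 1e-7, 100.0)
        m = curve_metrics(p)
        assert fourpl_eval(p, m.sensitivity) == pytest.approx(2.0 * m.basal, rel=1e-9)

    def test_sensitivity_flagged_nan_when_twofold_unreachable(self):
        # maximum below 2x basal: no dose produces a 2-fold change
        m = curve_metrics(FourPL(10.0, 1.0, 1e-7, 15.0))
        assert math.isnan(m.sensitivity)

    def test_inverted_curve_rejected(self):
        with pytest.raises(ValueError):
            curve_metrics(FourPL(10.0, 1.0, 1e-7, 1.0))


class TestGrowthRate:
    def test_constant_od_gives_zero(self):
        s = GrowthSeries(np.arange(0, 24.001, 0.25), np.full(97, 0.5))
        assert growth_rate(s, 2.0) == 0.0

    def test_doubling_every_three_hours(self):
        t = np.arange(0, 24.001, 0.25)
        s = GrowthSeries(t, 0.1 * 2 ** (t / 3.0))
        assert growth_rate(s, 5.0) == pytest.approx(math.log(2) / 3, rel=1e-9)

    def test_exponential_rate_identity(self):
        t = np.arange(0, 24.001, 0.25)
        for r in (0.05, 0.3, 0.7):
            s = GrowthSeries(t, 0.2 * np.exp(r * t))
            assert growth_rate(s, 1.7) == pytest.approx(r, rel=1e-9)

    def test_window_beyond_series_rejected(self):
        s = GrowthSeries(np.arange(0, 4.001, 0.25), np.full(17, 0.5))
        with pytest.raises(ValueError):
            growth_rate(s, 2.0)


class TestRSquared:
    def test_perfect_prediction(self):
        rep = r_squared([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert rep.r_squared == 1.0

    def test_mean_prediction_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = r_squared(y, np.full(3, y.mean()))
        assert rep.r_squared == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        rep = r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rep.r_squared == pytest.approx(0.5)
        assert rep.residuals == pytest.approx([0.0, 0.0, -1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 2.0])

    def test_least_squares_fit_beats_perturbations(self, example_fourpl, rng):
        doses = np.concatenate([[0.0], np.logspace(-10, -5, 12)])
        clean = fourpl_eval(example_fourpl, doses)
        noisy = clean * rng.lognormal(0, 0.05, clean.shape)
        fit, report = fit_fourpl(ResponseCurve(doses, noisy))
        for _ in range(20):
            jig = FourPL(
                fit.A * rng.uniform(0.9, 1.1),
                fit.B * rng.uniform(0.9, 1.1),
                fit.C * rng.uniform(0.9, 1.1),
                fit.D * rng.uniform(0.9, 1.1),
            )
            other = r_squared(noisy, fourpl_eval(jig, doses))
            assert report.r_squared >= other.r_squared - 1e-12


class TestComposeMixture:
    def test_identical_members_reproduce_member(self, example_fourpl):
        grid = np.logspace(-10, -5, 20)
        spec = MixtureSpec([example_fourpl] * 3, [1 / 3] * 3)
        mixed = compose_mixture(spec, grid)
        assert mixed.responses == pytest.approx(fourpl_eval(example_fourpl, grid))

    def test_degenerate_weights_select_single_member(self, example_fourpl):
        other = FourPL(0.0, 2.0, 1e-6, 500.0)
        grid = np.logspace(-10, -5, 20)
        mixed = compose_mixture(MixtureSpec([example_fourpl, other], [1.0, 0.0]), grid)
        assert mixed.responses == pytest.approx(fourpl_eval(example_fourpl, grid))

    def test_mixture_of_shifted_members_flattens_hill_slope(self):
        # the population-averaging linearization: equal-max members with
        # EC50s 100x apart fit to a shallower slope than either member
        m1 = FourPL(0.0, 1.5, 1e-8, 1.0)
        m2 = FourPL(0.0, 1.5, 1e-6, 1.0)
        grid = np.concatenate([[0.0], np.logspace(-10.5, -3.5, 25)])
        mixed = compose_mixture(MixtureSpec([m1, m2], [0.5, 0.5]), grid)
        fit, _ = fit_fourpl(mixed)
        assert fit.B < 1.5
        assert fit.B < min(m1.B, m2.B)

    def test_linear_in_weights_and_preserves_basal(self):
        m1 = FourPL(1.0, 1.0, 1e-8, 10.0)
        m2 = FourPL(3.0, 1.0, 1e-6, 30.0)
        grid = np.concatenate([[0.0], np.logspace(-9, -4, 10)])
        for w in (0.2, 0.5, 0.8):
            mixed = compose_mixture(MixtureSpec([m1, m2], [w, 1 - w]), grid)
            assert mixed.responses[0] == pytest.approx(w * m1.A + (1 - w) * m2.A)

    def test_invalid_weights_rejected(self, example_fourpl):
        with pytest.raises(ValueError):
            MixtureSpec([example_fourpl], [0.5])
        with pytest.raises(ValueError):
            MixtureSpec([example_fourpl, example_fourpl], [0.7, 0.7])


class TestSpanFoldChange:
    def test_reported_consortium_extension_is_fiftyfold(self):
        # single strain operational over 1.6 orders, consortium over 3.3:
        # the concentration-fold range widens ~50x
        assert span_fold_change(1.6, 3.3) == pytest.approx(50.0, rel=0.02)

    @pytest.mark.parametrize("s1, s2, expected", [(2.0, 3.0, 10.0), (1.4, 1.4, 1.0)])
    def test_closed_form(self, s1, s2, expected):
        assert span_fold_change(s1, s2) == pytest.approx(expected, rel=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    a=st.floats(0.0, 10.0),
    gap=st.floats(1.0, 1e4),
    b=st.floats(0.2, 8.0),
    logc=st.floats(-10.0, -5.0),
)
def test_fit_eval_round_trip_property(a, gap, b, logc):
    """Noise-free fit/eval round trip is the identity for any activating 4PL."""
    truth = FourPL(a, b, 10.0**logc, a + gap)
    doses = np.concatenate([[0.0], np.logspace(logc - 2.5, logc + 2.5, 14)])
    fit, report = fit_fourpl(ResponseCurve(doses, fourpl_eval(truth, doses)))
    assert report.r_squared == pytest.approx(1.0, abs=1e-9)
    assert math.log10(fit.C) == pytest.approx(logc, abs=1e-4)
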