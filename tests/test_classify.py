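"""Coordinate transforms, OLS fitting and decay-type classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rangelaw.classify import (InsufficientDataError, Transform,
                               classify_duration_curve, classify_range_curve,
                               fit_transform, ols_fit, transform_curve)
from rangelaw.curves import FittingCurve, exceedance_curve, trim_for_fitting
from rangelaw.models import DecayModel, survival_probability


def fitting_curve(x, y, axis_kind="duration_My", n_total=100):
    return FittingCurve(axis_kind=axis_kind, thresholds=np.asarray(x, float),
                        proportions=np.asarray(y, float), n_total=n_total,
                        sufficient=True)


class TestTransformCurve:
    def test_semilog_of_exact_exponential_has_slope_minus_one_over_ln10(self):
        x = np.linspace(0.5, 5, 10)
        curve = fitting_curve(x, np.exp(-x))
        tx, ty = transform_curve(curve, Transform("semilog", "duration"))
        slopes = np.diff(ty) / np.diff(tx)
        np.testing.assert_allclose(slopes, -1 / np.log(10), rtol=1e-12)

    def test_plain_is_identity(self):
        x, y = [1.0, 2.0], [0.5, 0.25]
        tx, ty = transform_curve(fitting_curve(x, y), Transform("plain", "duration"))
        np.testing.assert_array_equal(tx, x)
        np.testing.assert_array_equal(ty, y)

    def test_width_squared_equals_area_axis(self):
        curve = fitting_curve([2.0, 3.0, 4.0], [0.6, 0.3, 0.1], axis_kind="width_km")
        xw, _ = transform_curve(curve, Transform("plain", "width"))
        xa, _ = transform_curve(curve, Transform("plain", "area"))
        np.testing.assert_allclose(xa, np.square(xw))

    def test_proportion_at_bound_rejected(self):
        curve = fitting_curve([1.0, 2.0], [1.0, 0.5])
        with pytest.raises(ValueError):
            transform_curve(curve, Transform("semilog", "duration"))

    def test_loglog_requires_positive_thresholds(self):
        curve = fitting_curve([0.0, 2.0], [0.6, 0.5])
        with pytest.raises(ValueError):
            transform_curve(curve, Transform("loglog", "duration"))


class TestOlsFit:
    def test_collinear_points_r2_one(self):
        fit = ols_fit([1, 2, 3, 4], [2, 4, 6, 8])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self, rng):
        """Slope/intercept/R^2 agree with an independent textbook solve."""
        x = rng.uniform(0, 10, 5)
        y = 3.0 - 0.4 * x + rng.normal(0, 0.3, 5)
        fit = ols_fit(x, y)
        design = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.intercept == pytest.approx(beta[0])
        assert fit.slope == pytest.approx(beta[1])
        assert fit.r2 == pytest.approx(r2)

    def test_matches_statsmodels(self, rng):
        """Independent cross-check against a second OLS implementation."""
        import statsmodels.api as sm

        x = rng.uniform(0, 5, 12)
        y = 1.0 - 0.1 * x + rng.normal(0, 0.05, 12)
        fit = ols_fit(x, y)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(res.params[1])
        assert fit.r2 == pytest.approx(res.rsquared)

    def test_constant_y_zero_r2(self):
        fit = ols_fit([1, 2, 3], [0.5, 0.5, 0.5])
        assert fit.slope == 0.0
        assert fit.r2 == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([1, 1, 1], [1, 2, 3])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            ols_fit([1, 2], [1, 2])


class TestClassification:
    @pytest.mark.parametrize("model,x,expected", [
        (DecayModel("linear", (0.0666666, 1.0)), np.linspace(1, 13, 12), "Pln"),
        (DecayModel("exponential", (1.0, 1.0)), np.linspace(0.5, 5, 12), "LAW"),
        (DecayModel("power", (0.001, 3.0)), np.linspace(0.15, 0.9, 12), "Pow"),
    ])
    def test_noiseless_model_recovery(self, model, x, expected):
        """Each base decay model classifies to its own type with perfect fit
        in its native coordinates and imperfect fits elsewhere."""
        curve = fitting_curve(x, model.evaluate(x))
        decay = classify_duration_curve(curve)
        assert decay.label == expected
        assert decay.best.r2 == pytest.approx(1.0, abs=1e-10)
        assert not decay.weak
        others = [f.r2 for f in decay.fits if f is not decay.best]
        assert all(r2 < 1.0 - 1e-6 for r2 in others)

    def test_range_curve_exponential_widths_classify_law(self, rng):
        widths = rng.exponential(100.0, 5000)
        decay = classify_range_curve(
            trim_for_fitting(exceedance_curve(widths, "width_km")))
        assert decay.label == "LAW"

    def test_range_curve_exponential_areas_classify_law2(self, rng):
        areas = rng.exponential(1000.0, 5000)
        widths = np.sqrt(areas)
        decay = classify_range_curve(
            trim_for_fitting(exceedance_curve(widths, "width_km")))
        assert decay.label == "LAW2"

    def test_loglog_r2_identical_across_axes(self, rng):
        """log area is affine in log width, so the log-log fit is shared."""
        curve = trim_for_fitting(
            exceedance_curve(rng.exponential(50.0, 500), "width_km"))
        fw = fit_transform(curve, Transform("loglog", "width"))
        fa = fit_transform(curve, Transform("loglog", "area"))
        assert abs(fw.r2 - fa.r2) < 1e-10

    def test_insufficient_points_label(self):
        curve = FittingCurve("duration_My", np.array([1.0, 2.0]),
                             np.array([0.5, 0.2]), 10, sufficient=False)
        decay = classify_duration_curve(curve)
        assert decay.label == "insufficient"
        assert decay.formatted == "-"

    def test_weak_flag_and_formatting(self, rng):
        """A noisy curve whose best R^2 dips below 0.9 is parenthesised."""
        x = np.linspace(1, 10, 12)
        y = np.clip(np.exp(-x / 3) + rng.normal(0, 0.12, 12), 0.01, 0.99)
        decay = classify_duration_curve(fitting_curve(x, np.sort(y)[::-1]))
        if decay.best.r2 < 0.9:
            assert decay.weak and decay.formatted == f"({decay.label})"
        else:
            assert not decay.weak and decay.formatted == decay.label

    def test_plain_fit_invariant_to_y_rescaling(self):
        """R^2 ordering of the plain fit is unchanged by positive y scaling."""
        x = np.linspace(1, 10, 10)
        y = 0.9 - 0.05 * x + 0.01 * np.sin(x)
        r2a = ols_fit(x, y).r2
        r2b = ols_fit(x, 0.5 * y).r2
        assert r2a == pytest.approx(r2b, abs=1e-12)

    def test_semilog_fit_invariant_to_x_rescaling(self):
        x = np.linspace(0.5, 5, 10)
        y = np.log10(np.exp(-x) + 0.001)
        assert ols_fit(x, y).r2 == pytest.approx(ols_fit(3.7 * x, y).r2, abs=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(0.2, 5.0))
    def test_classification_invariant_to_threshold_scaling(self, scale):
        """Multiplying all thresholds by a positive constant preserves the
        winning transform (affine x under every candidate)."""
        rng = np.random.default_rng(42)
        widths = rng.exponential(30.0, 1000)
        a = classify_range_curve(trim_for_fitting(exceedance_curve(widths, "width_km")))
        b = classify_range_curve(trim_for_fitting(exceedance_curve(scale * widths, "width_km")))
        assert a.label == b.label


class TestSurvivalProbability:
    def test_exponential_is_age_independent(self):
        model = DecayModel("exponential", (1.0, 0.3))
        assert survival_probability(model, 1) == survival_probability(model, 100)
        assert survival_probability(model, 5) == pytest.approx(np.exp(-0.3))

    def test_exponential_zero_rate_certain_survival(self):
        assert survival_probability(DecayModel("exponential", (1.0, 0.0)), 7) == 1.0

    def test_linear_aging(self):
        """N0=10, c=1: survival 0.9 at t=0 falls to 0.5 at t=8."""
        model = DecayModel("linear", (1.0, 10.0))
        assert survival_probability(model, 0) == pytest.approx(0.9)
        assert survival_probability(model, 8) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            survival_probability(model, 10)

    def test_power_survival_improves_with_age(self):
        model = DecayModel("power", (0.001, 3.0))
        probs = [survival_probability(model, t) for t in (1, 5, 50)]
        assert probs == sorted(probs)
        assert survival_probability(model, 1) == pytest.approx(2.0 ** -3.0)
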