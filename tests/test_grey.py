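"""GM(1,1) grey model: accumulation algebra, closed-form fits, posterior
-deviation validation, degree grading, forecasting, and burden division."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import greyscan as gs
from greyscan.errors import DomainError
from greyscan.grey import GreySeries, accumulated_generation, mean_sequence

from conftest import GREY_VALIDATION_ADMISSION_ROWS, GREY_VALIDATION_IR_ROWS

positive_series = st.lists(st.floats(0.1, 1e4), min_size=4, max_size=12)


class TestAccumulation:
    def test_cumulative_sum(self):
        np.testing.assert_allclose(accumulated_generation([1, 2, 3]), [1, 3, 6])
        np.testing.assert_allclose(accumulated_generation([5]), [5])

    @given(positive_series)
    def test_first_differences_invert_accumulation_exactly(self, xs):
        y = accumulated_generation(xs)
        recovered = np.concatenate([[y[0]], np.diff(y)])
        np.testing.assert_allclose(recovered, xs, rtol=1e-9)

    def test_mean_sequence(self):
        np.testing.assert_allclose(mean_sequence([1, 3, 6]), [2.0, 4.5])
        assert mean_sequence(np.arange(5)).size == 4
        with pytest.raises(DomainError):
            mean_sequence([1.0])

    def test_constant_increments_give_arithmetic_progression(self):
        y = accumulated_generation([2.0] * 6)
        z = mean_sequence(y)
        np.testing.assert_allclose(np.diff(z), 2.0)


class TestFit:
    def test_geometric_series_closed_form(self):
        # x_t = a q^t satisfies the difference system exactly with
        # alpha = -2(q-1)/(q+1), mu = 2a/(q+1)
        m = gs.fit_gm11([1, 2, 4, 8])
        assert m.alpha == pytest.approx(-2.0 / 3.0, abs=1e-10)
        assert m.mu == pytest.approx(2.0 / 3.0, abs=1e-10)
        # the continuous reconstruction tracks the geometric input closely
        # but not exactly (e^{-alpha} != q: the discrete/continuous gap)
        np.testing.assert_allclose(m.fitted, [1, 2, 4, 8], rtol=0.11)
        assert m.fitted[0] == 1.0

    @given(st.floats(0.2, 3.0).filter(lambda q: abs(q - 1) > 1e-3),
           st.floats(0.5, 50.0))
    def test_geometric_closed_form_parametrized(self, q, a):
        xs = [a * q**t for t in range(6)]
        m = gs.fit_gm11(xs)
        assert m.alpha == pytest.approx(-2 * (q - 1) / (q + 1), rel=1e-8)
        assert m.mu == pytest.approx(2 * a / (q + 1), rel=1e-8)

    def test_constant_series_degenerate_linear_limit(self):
        m = gs.fit_gm11([5, 5, 5, 5])
        assert abs(m.alpha) < 1e-9
        assert m.mu == pytest.approx(5.0)
        np.testing.assert_allclose(m.fitted, 5.0)
        np.testing.assert_allclose(gs.forecast(m, 3), 5.0)

    def test_least_squares_agrees_with_grid_minimizer(self):
        # independent oracle: dense grid search over (alpha, mu) minimizing
        # the squared residual of x_t + alpha z_t - mu
        xs = np.array([3.0, 4.0, 6.0, 9.5])
        z = mean_sequence(accumulated_generation(xs))
        rhs = xs[1:]
        best = (np.inf, None, None)
        for alpha in np.linspace(-1.0, 0.2, 1201):
            for mu in np.linspace(0.0, 6.0, 1201):
                loss = np.sum((rhs + alpha * z - mu) ** 2)
                if loss < best[0]:
                    best = (loss, alpha, mu)
        m = gs.fit_gm11(xs)
        assert m.alpha == pytest.approx(best[1], abs=2e-3)
        assert m.mu == pytest.approx(best[2], abs=1e-2)
        # and the analytic solution is at least as good as the grid's best
        assert np.sum((rhs + m.alpha * z - m.mu) ** 2) <= best[0] + 1e-12

    @given(st.floats(-0.4, 0.4).filter(lambda a: abs(a) > 1e-3),
           st.floats(1.0, 20.0), st.floats(1.0, 20.0))
    def test_parameter_recovery_from_model_generated_series(self, alpha, mu, x0):
        # zero-residual series of the difference system:
        # x_t = (mu - alpha y_{t-1}) / (1 + alpha/2)
        xs, y = [x0], x0
        for _ in range(7):
            x = (mu - alpha * y) / (1.0 + alpha / 2.0)
            xs.append(x)
            y += x
        if np.any(np.asarray(xs) <= 0) or np.ptp(xs[1:]) < 1e-9:
            return
        m = gs.fit_gm11(xs)
        assert m.alpha == pytest.approx(alpha, abs=1e-6)
        assert m.mu == pytest.approx(mu, abs=1e-6)

    def test_series_validation(self):
        with pytest.raises(DomainError, match="at least 4"):
            GreySeries((1.0, 2.0, 3.0))
        with pytest.raises(DomainError, match="> 0"):
            GreySeries((1.0, -2.0, 3.0, 4.0))


class TestValidation:
    def test_perfect_fit_grades_excellent(self):
        # validating a model against its own reconstruction: delta == 0
        m = gs.fit_gm11([1, 2, 4, 8])
        s1, s2, c, p = gs.validate_gm11(m, m.fitted)
        assert s2 == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0
        assert m.degree == "excellent"

    @pytest.mark.parametrize(
        "label, s1, s2, c_printed, p, degree",
        GREY_VALIDATION_IR_ROWS + GREY_VALIDATION_ADMISSION_ROWS,
    )
    def test_posterior_ratio_matches_worked_examples(self, label, s1, s2, c_printed, p, degree):
        assert s2 / s1 == pytest.approx(c_printed, abs=1e-4)

    @pytest.mark.parametrize(
        "c, p, degree",
        [(row[3], row[4], row[5]) for row in GREY_VALIDATION_IR_ROWS + GREY_VALIDATION_ADMISSION_ROWS]
        + [(0.7, 0.5, "unreliable"), (0.64, 0.71, "marginal"), (0.49, 0.81, "good")],
    )
    def test_degree_grading(self, c, p, degree):
        assert gs.classify_degree(c, p) == degree

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 0.3), st.floats(0.0, 0.3))
    def test_degree_monotone_in_c_and_p(self, c, p, dc, dp):
        order = ["excellent", "good", "marginal", "unreliable"]
        base = order.index(gs.classify_degree(c + dc, max(0.0, p - dp)))
        better = order.index(gs.classify_degree(c, min(1.0, p)))
        assert better <= base

    def test_zero_variance_series_flagged_degenerate(self):
        m = gs.fit_gm11([5, 5, 5, 5])
        with pytest.warns(UserWarning, match="zero-variance"):
            s1, s2, c, p = gs.validate_gm11(m, [5, 5, 5, 5])
        assert np.isnan(c)


class TestForecast:
    def test_horizon_must_be_positive(self):
        m = gs.fit_gm11([1, 2, 4, 8])
        with pytest.raises(DomainError):
            gs.forecast(m, 0)

    def test_growth_fit_forecasts_increase(self):
        m = gs.fit_gm11([1, 2, 4, 8])
        fc = gs.forecast(m, 4)
        assert np.all(np.diff(fc) > 0)
        # next step of the continuous reconstruction: x_hat_{n+1} = x_hat_n e^{-alpha}
        assert fc[0] == pytest.approx(m.fitted[-1] * np.exp(-m.alpha), rel=1e-9)

    def test_decay_fit_forecasts_strictly_decreasing_positive(self):
        m = gs.fit_gm11([100.0, 70.0, 50.0, 36.0, 26.0])
        assert m.alpha > 0
        fc = gs.forecast(m, 5)
        assert np.all(np.diff(fc) < 0)
        assert np.all(fc > 0)

    def test_forecast_continues_the_fitted_reconstruction(self):
        xs = [3.0, 4.5, 6.1, 8.9, 12.0]
        m = gs.fit_gm11(xs)
        both = np.concatenate([m.fitted, gs.forecast(m, 3)])
        y = np.cumsum(both)
        t = np.arange(len(both), dtype=float)
        np.testing.assert_allclose(y, m.accumulated_at(t), rtol=1e-9)


class TestBurden:
    def test_elementwise_division(self):
        out = gs.burden({"A": [100.0]}, {"A": 4})
        np.testing.assert_allclose(out["A"], [25.0])
        out = gs.burden({"A": [0.0, 0.0]}, {"A": 3})
        np.testing.assert_allclose(out["A"], 0.0)

    def test_zero_hospitals_with_demand_names_district(self):
        with pytest.raises(DomainError, match="NoHosp"):
            gs.burden({"NoHosp": [10.0]}, {"NoHosp": 0})

    def test_burden_ranking_can_invert_admission_ranking(self):
        fc = {"big": [300.0], "mid": [200.0], "small": [100.0]}
        hospitals = {"big": 30, "mid": 10, "small": 2}
        b = gs.burden(fc, hospitals)
        by_admissions = sorted(fc, key=lambda d: -fc[d][0])
        by_burden = sorted(b, key=lambda d: -b[d][0])
        assert by_admissions[0] == "big" and by_burden[0] == "small"
        assert by_admissions != by_burden
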