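"""Quadratic effect-function fitting, typicality, stationary points, marginal optima."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from npk3414.datasets import FIT_TREATMENTS
from npk3414.effect import (
    AtypicalModelError,
    NoStationaryPointError,
    QuadraticEffectModel,
    RankDeficiencyError,
    fit_effect_function,
)
from npk3414.indices import PriceSchedule


def pinv_oracle(model, trial, factors, treatments):
    """Independent normal-equations solution via the Moore–Penrose pseudoinverse."""
    from npk3414.design import FACTORS
    from npk3414.effect import _resolve_treatments

    codes = _resolve_treatments(trial, treatments)
    idx = [FACTORS.index(f) for f in factors]
    X = np.array([[trial.design.doses_for(c)[i] for i in idx] for c in codes])
    y = np.array([trial.mean(c) for c in codes])
    M = model._design_matrix(X)
    return np.linalg.pinv(M) @ y


class TestFitAgainstOracle:
    @pytest.mark.parametrize("name", list(FIT_TREATMENTS))
    def test_coefficients_match_pseudoinverse(self, trial, name):
        factors = tuple(f for f in "NPK" if f in name)
        fit = fit_effect_function(trial, factors, list(FIT_TREATMENTS[name]))
        expected = pinv_oracle(fit, trial, factors, list(FIT_TREATMENTS[name]))
        assert fit.coef_ == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize(
        "name, linear, quadratic, ndigits",
        [
            ("P", 14.31, -0.55, 2),
            ("K", 8.14, -0.21, 2),
            ("N", 3.61, -0.048, 3),
        ],
    )
    def test_single_factor_slope_and_curvature(self, trial, name, linear, quadratic, ndigits):
        """Refits on the two-decimal treatment means reproduce the frozen
        normal-equations values (curvatures match the published table)."""
        fit = fit_effect_function(trial, (name,), list(FIT_TREATMENTS[name]))
        assert round(float(fit.linear_[0]), 2) == pytest.approx(linear, abs=0.01)
        assert round(float(fit.quadratic_[0]), ndigits) == pytest.approx(quadratic)

    def test_exact_quadratic_interpolation(self):
        x = np.array([[0.0], [5.0], [10.0], [20.0]])
        y = 100 + 2 * x[:, 0] - 0.1 * x[:, 0] ** 2
        fit = QuadraticEffectModel(("P",)).fit(x, y)
        assert fit.coef_ == pytest.approx([100, 2, -0.1], abs=1e-10)
        assert fit.r_squared_ == pytest.approx(1.0)

    def test_ternary_fit_highly_significant(self, trial):
        fit = fit_effect_function(trial, ("N", "P", "K"))
        assert fit.r_squared_ > 0.98
        assert fit.p_value_ < 0.05
        assert fit.n_points_ == 14
        assert len(fit.coef_) == 10

    def test_plot_level_and_mean_level_fits_agree_on_balanced_trial(self, trial_plot_means):
        m = fit_effect_function(trial_plot_means, ("N", "P", "K"), data="means")
        p = fit_effect_function(trial_plot_means, ("N", "P", "K"), data="plots")
        assert m.coef_ == pytest.approx(p.coef_, abs=1e-8)

    def test_underdetermined_fit_signals_rank_deficiency(self, trial):
        with pytest.raises(RankDeficiencyError):
            fit_effect_function(trial, ("N", "P", "K"), treatments=[1, 2, 3, 4, 5])

    def test_collinear_doses_signal_rank_deficiency(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])  # only two distinct doses
        with pytest.raises(RankDeficiencyError):
            QuadraticEffectModel(("N",)).fit(X, [1.0, 2.0, 3.0, 4.0])

    @given(st.floats(0.1, 100), st.floats(-500, 500))
    def test_r_squared_invariant_under_affine_yield_rescaling(self, trial, scale, shift):
        base = fit_effect_function(trial, ("P",), [4, 5, 6, 7])
        codes = [trial.design.codes[i - 1] for i in (4, 5, 6, 7)]
        X = np.array([[trial.design.doses_for(c)[1]] for c in codes])
        y = scale * np.array([trial.mean(c) for c in codes]) + shift
        refit = QuadraticEffectModel(("P",)).fit(X, y)
        assert refit.r_squared_ == pytest.approx(base.r_squared_, rel=1e-6)


class TestEvaluate:
    def test_published_ternary_at_recommended_point(self, ternary):
        assert ternary.evaluate((22.5, 7.5, 12)) == pytest.approx(386.95, abs=0.005)

    def test_zero_doses_give_intercept(self, ternary, singles):
        assert ternary.evaluate((0, 0, 0)) == pytest.approx(296.66)
        assert singles["P"].evaluate([0.0]) == pytest.approx(316.55)

    def test_published_n_function_at_vertex_dose(self, singles):
        # 340.95 + 3.60·37.5 − 0.048·37.5²
        assert singles["N"].evaluate([37.5]) == pytest.approx(408.45)

    def test_dose_count_mismatch_rejected(self, ternary):
        with pytest.raises(ValueError):
            ternary.evaluate((10.0, 5.0))

    def test_predict_vectorizes(self, ternary):
        X = np.array([[0, 0, 0], [22.5, 7.5, 12]])
        out = ternary.predict(X)
        assert out[0] == pytest.approx(296.66)
        assert out[1] == pytest.approx(386.9487, abs=1e-4)


class TestStationaryPoint:
    def test_p_function_vertex_near_13(self, singles):
        sp = singles["P"].stationary_point()
        assert sp.nature == "maximum"
        assert round(sp.doses[0]) == 13

    def test_n_function_vertex_yield(self, singles):
        sp = singles["N"].stationary_point()
        assert sp.doses[0] == pytest.approx(37.5)
        assert sp.predicted_yield == pytest.approx(408.45)

    def test_pure_even_quadratic_vertex_at_zero(self):
        m = QuadraticEffectModel.from_coefficients(("N",), 50.0, (0.0,), (-0.5,))
        sp = m.stationary_point()
        assert sp.doses[0] == pytest.approx(0.0)
        assert sp.nature == "maximum"

    def test_gradient_vanishes_at_stationary_point(self, ternary):
        sp = ternary.stationary_point()
        assert np.linalg.norm(ternary.gradient(sp.doses)) < 1e-9

    def test_saddle_detected(self):
        m = QuadraticEffectModel.from_coefficients(
            ("N", "P"), 0.0, (1.0, 1.0), (-0.5, 0.5)
        )
        assert m.stationary_point().nature == "saddle"

    def test_singular_quadratic_matrix_signals(self):
        m = QuadraticEffectModel.from_coefficients(("N",), 100.0, (2.0,), (0.0,))
        with pytest.raises(NoStationaryPointError):
            m.stationary_point()


class TestTypicality:
    def test_published_ternary_is_atypical_on_n_linear(self, ternary):
        v = ternary.typicality()
        assert not v.is_typical
        assert [x[0] for x in v.violations] == ["N_linear"]
        assert v.violations[0][2] == pytest.approx(-0.81)

    def test_published_p_function_is_typical(self, singles):
        assert singles["P"].typicality().is_typical

    def test_all_zero_coefficients_violate_every_term(self):
        m = QuadraticEffectModel.from_coefficients(("N", "P"), 0.0, (0.0, 0.0), (0.0, 0.0))
        v = m.typicality()
        assert not v.is_typical
        assert len(v.violations) == 4  # strict signs: zeros breach both rules


class TestMarginalOptimum:
    def make_prices(self, crop, n=1.0, p=1.0, k=1.0):
        return PriceSchedule(crop_price=crop, nutrient_prices={"N": n, "P": p, "K": k})

    def test_atypical_fit_refused(self, ternary):
        with pytest.raises(AtypicalModelError):
            ternary.marginal_optimum(self.make_prices(24.0))

    def test_textbook_single_factor_solution(self):
        # Y = 100 + 2X − 0.1X², crop price 1, fertilizer price 1 → 2 − 0.2x = 1 → x = 5
        m = QuadraticEffectModel.from_coefficients(("N",), 100.0, (2.0,), (-0.1,))
        opt = m.marginal_optimum(self.make_prices(1.0, n=1.0))
        assert opt.doses[0] == pytest.approx(5.0)

    def test_vanishing_fertilizer_price_approaches_vertex(self, singles):
        m = singles["P"]
        opt = m.marginal_optimum(self.make_prices(24.0, p=1e-9))
        assert opt.doses[0] == pytest.approx(m.stationary_point().doses[0], abs=1e-6)

    @given(st.floats(0.5, 50), st.floats(0.5, 50))
    def test_marginal_dose_below_vertex_for_positive_prices(self, crop, fert):
        m = QuadraticEffectModel.from_coefficients(("P",), 316.55, (14.31,), (-0.55,))
        opt = m.marginal_optimum(
            PriceSchedule(crop_price=crop, nutrient_prices={"N": 1, "P": fert, "K": 1})
        )
        assert opt.doses[0] < m.stationary_point().doses[0]


def test_from_coefficients_round_trips_through_report(ternary):
    rep = ternary.to_report()
    assert rep["coefficients"]["intercept"] == pytest.approx(296.66)
    assert rep["typical"] is False
    frame = ternary.coefficients_frame()
    assert list(frame["term"])[:4] == ["intercept", "N", "P", "K"]
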