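"""Detrended AB regression: trend fit, de-trend scores, level/slope effects."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scedbehave.model import phase_slice
from scedbehave.parametric import (
    BaselineTrend,
    DetrendSeries,
    analyze_parametric,
    check_covariance_assumption,
    detrend,
    fit_baseline_trend,
    fit_effect_model,
)

from .conftest import make_series


def ds_from_phases(A, B):
    n_a, n_b = len(A), len(B)
    t = np.arange(1, n_a + n_b + 1, dtype=float)
    return DetrendSeries(
        t=t,
        d=np.asarray(A + B, dtype=float),
        phase_indicator=np.concatenate([np.zeros(n_a), np.ones(n_b)]),
        n_A=n_a,
        n_B=n_b,
    )


class TestBaselineTrend:
    def test_flat_zero_baseline_gives_zero_line(self):
        tr = fit_baseline_trend([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert (tr.intercept, tr.slope) == (0.0, 0.0)

    def test_collinear_input_is_exact(self):
        tr = fit_baseline_trend([1, 2, 3], [1, 2, 3])
        assert tr.intercept == pytest.approx(0.0, abs=1e-12)
        assert tr.slope == pytest.approx(1.0)

    def test_closed_form_ols(self):
        tr = fit_baseline_trend([1, 2, 3], [2, 1, 3])
        assert (tr.intercept, tr.slope) == pytest.approx((1.0, 0.5))

    def test_too_short_baseline_rejected(self):
        with pytest.raises(ValueError):
            fit_baseline_trend([1], [3])


class TestDetrend:
    def test_zero_trend_is_identity(self):
        s = make_series({"A": [1, 2], "B": [5, 6, 7]})
        ds = detrend(s, BaselineTrend(0.0, 0.0, 2))
        assert list(ds.d) == [1, 2, 5, 6, 7]

    def test_fitted_line_is_subtracted_everywhere(self):
        s = make_series({"A": [1, 2, 3], "B": [10, 11]})
        ds = detrend(s, BaselineTrend(0.0, 1.0, 3))
        assert list(ds.d) == [0, 0, 0, 6, 6]
        assert ds.t_B == 4

    def test_baseline_residuals_sum_to_zero(self):
        s = make_series({"A": [2, 1, 3, 7, 4], "B": [9, 12, 15, 11, 13]})
        ta, ya = phase_slice(s, "A")
        ds = detrend(s, fit_baseline_trend(ta, ya))
        assert float(ds.d[ds.phase_indicator == 0].sum()) == pytest.approx(0, abs=1e-9)


class TestEffectModel:
    def test_exact_mean_separation(self):
        res = fit_effect_model(ds_from_phases([0, 0, 0], [6, 6, 6]))
        assert res.c1 == pytest.approx(6.0)
        assert res.c2 == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == 1.0
        assert res.exact_fit
        assert res.p_value == 0.0
        assert math.isinf(res.f_stat)

    def test_constant_detrend_scores_give_null_fit(self):
        res = fit_effect_model(ds_from_phases([3, 3, 3], [3, 3, 3]))
        assert res.r_squared == 0.0
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_f_r2_identity_at_case_study_size(self):
        # R^2 = 0.83 at n = 35 implies F(2, 32) = 78.12 via the identity
        rng = np.random.default_rng(5)
        # construct any series, then check the identity on its own numbers
        res = fit_effect_model(
            ds_from_phases(list(rng.normal(0, 1, 5)), list(rng.normal(3, 1, 30)))
        )
        n = 35
        expect = (res.r_squared / 2) / ((1 - res.r_squared) / (n - 3))
        assert res.f_stat == pytest.approx(expect, rel=1e-12)
        assert res.df == (2, 32)
        assert (0.83 / 2) / ((1 - 0.83) / 32) == pytest.approx(78.12, abs=0.01)

    def test_r_is_signed_square_root_of_r2(self):
        up = fit_effect_model(ds_from_phases([0, 1, 0], [5, 6, 7, 6]))
        assert up.r == pytest.approx(math.sqrt(up.r_squared))
        down = fit_effect_model(ds_from_phases([5, 6, 5], [0, 1, 0, 1]))
        assert down.r == pytest.approx(-math.sqrt(down.r_squared))
        mirrored = fit_effect_model(
            ds_from_phases([5, 6, 5], [0, 1, 0, 1]), direction="decrease"
        )
        assert mirrored.r == pytest.approx(math.sqrt(down.r_squared))

    def test_centering_choice_does_not_move_fit_statistics(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ds = ds_from_phases(
                list(rng.normal(0, 1, 4)), list(rng.normal(2, 1, rng.integers(3, 12)))
            )
            res = fit_effect_model(ds)
            # recentre the interaction regressor at the mean treatment time
            n = ds.t.size
            tc = ds.t - ds.t[ds.phase_indicator == 1].mean()
            X = np.column_stack([np.ones(n), ds.phase_indicator, ds.phase_indicator * tc])
            beta, *_ = np.linalg.lstsq(X, ds.d, rcond=None)
            sse = float(((ds.d - X @ beta) ** 2).sum())
            sst = float(((ds.d - ds.d.mean()) ** 2).sum())
            r2 = 1 - sse / sst
            assert r2 == pytest.approx(res.r_squared, abs=1e-10)

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        ds = ds_from_phases(list(rng.normal(0, 1, 5)), list(rng.normal(2, 1.5, 12)))
        X = sm.add_constant(
            np.column_stack(
                [ds.phase_indicator, ds.phase_indicator * (ds.t - ds.t_B)]
            )
        )
        fit = sm.OLS(ds.d, X).fit()
        res = fit_effect_model(ds)
        assert res.r_squared == pytest.approx(fit.rsquared, rel=1e-10)
        assert res.f_stat == pytest.approx(fit.fvalue, rel=1e-10)
        assert res.p_value == pytest.approx(fit.f_pvalue, rel=1e-8)
        assert (res.c0, res.c1, res.c2) == pytest.approx(tuple(fit.params), rel=1e-9)

    def test_collinear_design_rejected(self):
        ds = ds_from_phases([0, 0], [1, 2, 3])
        bad = DetrendSeries(
            t=np.full_like(ds.t, 3.0), d=ds.d, phase_indicator=ds.phase_indicator,
            n_A=2, n_B=3,
        )
        with pytest.raises(ValueError):
            fit_effect_model(bad)


class TestCovarianceAssumption:
    def test_upward_separation_meets_assumption(self):
        flag, cov = check_covariance_assumption(ds_from_phases([0, 0, 0], [6, 6, 6]))
        assert flag and cov > 0

    def test_constant_scores_fail(self):
        flag, cov = check_covariance_assumption(ds_from_phases([3, 3], [3, 3]))
        assert not flag and cov == 0.0

    def test_direction_mirrors_the_sign(self):
        ds = ds_from_phases([6, 6], [0, 0])
        assert check_covariance_assumption(ds, "increase")[0] is False
        assert check_covariance_assumption(ds, "decrease")[0] is True


class TestPipeline:
    def test_flat_zero_baseline_series_gives_detrend_equal_raw(self, series_5a30b):
        ta, ya = phase_slice(series_5a30b, "A")
        ds = detrend(series_5a30b, fit_baseline_trend(ta, ya))
        _, yb = phase_slice(series_5a30b, "B")
        assert list(ds.d) == list(ya) + list(yb)

    def test_toy_flat_phases_fit_exactly(self):
        s = make_series({"A": [0, 0, 0], "B": [6, 6, 6]})
        res = analyze_parametric(s)
        assert res.r_squared == 1.0 and res.exact_fit
        assert res.cov_assumption_met and res.cov_value > 0

    def test_assumption_failure_does_not_abort(self):
        s = make_series({"A": [6, 7, 6], "B": [1, 0, 1, 0]})
        res = analyze_parametric(s)  # direction=increase, behavior got worse
        assert res.cov_assumption_met is False
        assert res.r < 0

    def test_case_study_shape_reports_large_signed_r(self, series_5a30b):
        res = analyze_parametric(series_5a30b)
        assert res.df == (2, 32)
        assert res.r > 0.9
        assert res.p_value < 0.05


@given(
    st.lists(st.integers(0, 50), min_size=3, max_size=6),
    st.lists(st.integers(0, 50), min_size=3, max_size=12),
)
@settings(max_examples=100, deadline=None)
def test_f_r2_identity_holds_on_random_series(A, B):
    ds = ds_from_phases([float(a) for a in A], [float(b) for b in B])
    try:
        res = fit_effect_model(ds)
    except ValueError:
        return  # collinear by construction; out of this property's scope
    if not res.exact_fit:
        n = len(A) + len(B)
        assert res.f_stat == pytest.approx(
            (res.r_squared / 2) / ((1 - res.r_squared) / (n - 3)), rel=1e-9, abs=1e-9
        )
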