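"""Method selection, interpretation bands, milestones and report assembly."""

import itertools

import pytest

from scedbehave.engine import (
    AssumptionFlags,
    DEFAULT_BAND_TABLES,
    ReportConfig,
    build_report,
    detect_mastery,
    first_session_meeting,
    interpret,
    phase_trend,
    score_at_least,
    score_is_max,
    score_positive,
    select_method,
)

from .conftest import make_series


class TestSelectMethod:
    def test_case_study_sizes_choose_parametric(self):
        flags = AssumptionFlags(True, False, True)
        sel = select_method(5, 30, flags)
        assert sel.method == "parametric"
        assert sel.rule_id == "R1-parametric"

    def test_tiny_baseline_falls_back_to_nap(self):
        sel = select_method(2, 4, AssumptionFlags(True, False, True))
        assert sel.method == "nap" and sel.rule_id == "R3-nap"

    def test_failed_covariance_with_trending_baseline_uses_tau_u(self):
        sel = select_method(5, 30, AssumptionFlags(True, True, False))
        assert sel.method == "tau_u" and sel.rule_id == "R2-tau-u"

    def test_selection_is_pure_over_the_whole_grid(self):
        for n_a, n_b, tv, tr, cov in itertools.product(
            range(1, 8), range(1, 12), *([(False, True)] * 3)
        ):
            flags = AssumptionFlags(tv, tr, cov)
            a = select_method(n_a, n_b, flags)
            b = select_method(n_a, n_b, flags)
            assert (a.method, a.rule_id) == (b.method, b.rule_id)
            if a.method == "parametric":
                assert n_a >= 3 and n_b >= 5 and tv and cov
            elif a.method == "tau_u":
                assert n_a >= 3 and tr
            assert a.inputs["n_A"] == n_a


class TestInterpretationBands:
    @pytest.mark.parametrize(
        "method, estimate, band",
        [
            ("PARAMETRIC_R", 0.95, "large"),
            ("PARAMETRIC_R", -0.95, "large"),  # magnitude, not sign
            ("NAP", 0.5, "weak"),
            ("NAP", 0.80, "medium"),
            ("TAU_U", 0.1, "weak"),
            ("PEM", 95.0, "large"),
        ],
    )
    def test_band_assignment(self, method, estimate, band):
        assert interpret(method, estimate).band == band

    def test_boundaries_fall_in_the_higher_band(self):
        for method, tab in DEFAULT_BAND_TABLES.items():
            assert interpret(method, tab["medium"]).band == "medium"
            assert interpret(method, tab["large"]).band == "large"

    def test_gauge_position_rescales_native_range(self):
        assert interpret("NAP", 0.75).gauge_position == pytest.approx(0.75)
        assert interpret("TAU_U", 0.0).gauge_position == pytest.approx(0.5)
        assert interpret("PND", 100.0).gauge_position == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            interpret("BANANA", 0.5)


class TestMilestones:
    def test_all_zero_series_has_no_first_response(self):
        s = make_series({"A": [0] * 5, "B": [0] * 6})
        assert first_session_meeting(s, score_positive) is None

    def test_first_response_counted_on_global_axis(self):
        s = make_series({"A": [0] * 5, "B": [0, 0, 3, 10, 20]})
        assert first_session_meeting(s, score_positive) == 8

    def test_first_max_score_scan(self):
        scores = [0] * 30 + [48, 49, 50, 50]
        s = make_series({"A": scores[:5], "B": scores[5:]})
        assert first_session_meeting(s, score_is_max) == 33

    def test_mastery_returns_last_session_of_the_run(self):
        b = [0] * 14 + [40, 41, 43] + [45] * 13  # run of >=40 ends at session 22
        s = make_series({"A": [0] * 5, "B": b})
        assert detect_mastery(s, 0.8, 3) == 22

    def test_mastery_run_restarts_after_a_dip(self):
        s = make_series({"A": [0, 0], "B": [45, 45, 10, 45, 45, 45]})
        assert detect_mastery(s, 0.8, 3) == 8

    def test_no_mastery_on_all_zero_series(self):
        s = make_series({"A": [0] * 5, "B": [0] * 10})
        assert detect_mastery(s) is None

    def test_single_session_mastery_equals_first_meeting(self):
        s = make_series({"A": [0] * 3, "B": [10, 44, 20, 41]})
        assert detect_mastery(s, 0.8, 1) == first_session_meeting(
            s, score_at_least(0.8)
        )


class TestPhaseTrend:
    def test_exact_line(self, series_with_g=None):
        s = make_series({"A": [0, 0], "B": [1, 1], "G": [10, 20, 30]})
        assert phase_trend(s, "G") == pytest.approx(10.0)

    def test_constant_phase_has_zero_trend(self):
        s = make_series({"A": [4, 4, 4], "B": [4, 4]})
        assert phase_trend(s, "A") == 0.0

    def test_closed_form_ols_slope(self):
        # Sxy = 13, Sxx = 5 -> 2.6
        s = make_series({"A": [0, 0], "B": [1, 1], "G": [5, 9, 8, 14]})
        assert phase_trend(s, "G") == pytest.approx(2.6)

    def test_short_phase_rejected(self):
        s = make_series({"A": [0], "B": [1, 2]})
        with pytest.raises(ValueError):
            phase_trend(s, "A")


class TestBuildReport:
    def test_case_study_shape_headlines_parametric_large(self, series_5a30b):
        rep = build_report(series_5a30b)
        assert rep.headline_method == "parametric"
        assert rep.band.band == "large"
        assert rep.parametric["df"] == [2, 32]
        assert set(rep.effect_sizes) == {"NAP", "PND", "PEM", "TAU_AB", "TAU_U"}

    def test_one_session_baseline_downgrades_to_nap(self):
        s = make_series({"A": [0], "B": [5, 9, 12, 15, 20, 22]})
        rep = build_report(s)
        assert rep.headline_method == "nap"
        assert rep.selection.rule_id == "R3-nap"
        assert rep.parametric is None
        assert "TAU_U" not in rep.effect_sizes

    def test_report_is_deterministic(self, series_5a30b):
        a = build_report(series_5a30b).to_json()
        b = build_report(series_5a30b).to_json()
        assert a == b

    def test_assumption_failure_surfaces_in_caveats(self):
        s = make_series({"A": [6, 7, 6], "B": [1, 0, 1, 0, 1]})
        rep = build_report(s, ReportConfig(method="parametric"))
        assert any("NOT met" in c for c in rep.caveats)
        md = rep.to_markdown()
        assert "Caveats" in md

    def test_forced_method_overrides_selector(self, series_5a30b):
        rep = build_report(series_5a30b, ReportConfig(method="tau_u"))
        assert rep.headline_method == "tau_u"
        assert rep.headline_estimate == rep.effect_sizes["TAU_U"]
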