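"""Analysis engine: method selection, interpretation bands, milestones, reports.

Mirrors the decision-support layer of a SCED monitoring tool: given a case
series it picks the most defensible effect-size method for the available
data (a deterministic, logged rule table), computes all applicable effect
sizes, maps the headline estimate to a qualitative band (the "speedometer"
reading: weak / medium / large), scans for clinical milestones (first
response, mastery criterion) and assembles everything into a deterministic
report.

Selection rule table (always logged with the rule id that fired):

* ``R1-parametric`` — detrended regression iff n_A >= 3, n_B >= 5, the
  baseline times have positive variance and the covariance assumption
  holds;
* ``R2-tau-u`` — otherwise Tau-U iff n_A >= 3 and the baseline shows a
  nonzero trend (Tau-U exists precisely to absorb baseline trend);
* ``R3-nap`` — otherwise NAP, the assumption-light floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model import CaseSeries, phase_slice, validate_series
from . import nonoverlap as no
from .parametric import (
    ANTICONSERVATISM_CAVEAT,
    ParametricResult,
    analyze_parametric,
    check_covariance_assumption,
    detrend,
    fit_baseline_trend,
)

__all__ = [
    "AssumptionFlags",
    "MethodSelection",
    "InterpretationBand",
    "ReportConfig",
    "AnalysisReport",
    "DEFAULT_BAND_TABLES",
    "select_method",
    "interpret",
    "first_session_meeting",
    "detect_mastery",
    "phase_trend",
    "build_report",
    "score_positive",
    "score_at_least",
    "score_is_max",
]


@dataclass(frozen=True)
class AssumptionFlags:
    baseline_time_variance_positive: bool
    baseline_trend_nonzero: bool
    cov_assumption_met: bool


@dataclass(frozen=True)
class MethodSelection:
    method: str  # parametric | tau_u | nap
    rule_id: str
    inputs: dict


# Band tables: (lower bound of medium, lower bound of large) on the scale
# named in `scale`.  Boundaries are closed below: an estimate exactly at a
# threshold falls in the higher band.
DEFAULT_BAND_TABLES = {
    "NAP": {"scale": "native", "medium": 0.66, "large": 0.93},
    "PND": {"scale": "native", "medium": 70.0, "large": 90.0},
    "PEM": {"scale": "native", "medium": 70.0, "large": 90.0},
    "TAU_AB": {"scale": "abs", "medium": 0.2, "large": 0.6},
    "TAU_U": {"scale": "abs", "medium": 0.2, "large": 0.6},
    "PARAMETRIC_R": {"scale": "abs", "medium": 0.3, "large": 0.5},
}

# native scale ranges used to place the speedometer needle in [0, 1]
_SCALE_RANGE = {
    "NAP": (0.0, 1.0),
    "PND": (0.0, 100.0),
    "PEM": (0.0, 100.0),
    "TAU_AB": (-1.0, 1.0),
    "TAU_U": (-1.0, 1.0),
    "PARAMETRIC_R": (-1.0, 1.0),
}


@dataclass(frozen=True)
class InterpretationBand:
    band: str  # weak | medium | large
    method: str
    thresholds: dict
    gauge_position: float  # estimate rescaled to [0, 1]


@dataclass(frozen=True)
class ReportConfig:
    direction: str = "increase"
    alpha: float = 0.05
    phases: tuple[str, str] = ("A", "B")
    method: str = "auto"  # auto | parametric | nap | pnd | pem | tau_ab | tau_u
    mastery_threshold: float = 0.8
    mastery_consecutive: int = 3
    band_tables: dict = field(default_factory=lambda: DEFAULT_BAND_TABLES)


def select_method(n_A: int, n_B: int, flags: AssumptionFlags) -> MethodSelection:
    """Deterministic method choice from phase sizes and assumption flags."""
    inputs = {
        "n_A": n_A,
        "n_B": n_B,
        "baseline_time_variance_positive": flags.baseline_time_variance_positive,
        "baseline_trend_nonzero": flags.baseline_trend_nonzero,
        "cov_assumption_met": flags.cov_assumption_met,
    }
    if (
        n_A >= 3
        and n_B >= 5
        and flags.baseline_time_variance_positive
        and flags.cov_assumption_met
    ):
        return MethodSelection("parametric", "R1-parametric", inputs)
    if n_A >= 3 and flags.baseline_trend_nonzero:
        return MethodSelection("tau_u", "R2-tau-u", inputs)
    return MethodSelection("nap", "R3-nap", inputs)


def interpret(
    method: str, estimate: float, band_tables: Optional[dict] = None
) -> InterpretationBand:
    """Map an effect-size estimate to its qualitative band and gauge position.

    ``method`` is one of the keys of :data:`DEFAULT_BAND_TABLES` (the
    parametric r uses ``"PARAMETRIC_R"``).  Thresholds are closed below.
    """
    tables = band_tables or DEFAULT_BAND_TABLES
    if method not in tables:
        raise ValueError(f"unknown method id {method!r}")
    tab = tables[method]
    value = abs(estimate) if tab["scale"] == "abs" else estimate
    if value >= tab["large"]:
        band = "large"
    elif value >= tab["medium"]:
        band = "medium"
    else:
        band = "weak"
    lo, hi = _SCALE_RANGE[method]
    gauge = float(np.clip((estimate - lo) / (hi - lo), 0.0, 1.0))
    return InterpretationBand(band=band, method=method, thresholds=dict(tab), gauge_position=gauge)


def score_positive(session) -> bool:
    return session.score > 0


def score_at_least(fraction: float):
    def pred(session) -> bool:
        return session.score >= fraction * session.max_score

    return pred


def score_is_max(session) -> bool:
    return session.score == session.max_score


def first_session_meeting(series: CaseSeries, predicate) -> Optional[int]:
    """Smallest global session index whose session satisfies ``predicate``.

    Indices are global (baseline included), so "first response in session
    8" means the 3rd training session of a 5-session baseline series.
    """
    for s in series.sessions:
        if predicate(s):
            return s.session_index
    return None


def detect_mastery(
    series: CaseSeries, threshold_fraction: float = 0.8, consecutive: int = 3
) -> Optional[int]:
    """Global index at which the mastery criterion is reached, or None.

    The criterion is ``consecutive`` sessions in a row all scoring at least
    ``threshold_fraction * max_score``; the returned index is the *last*
    session of the first qualifying run (the session at which mastery is
    attained).  With ``consecutive=1`` this reduces to
    :func:`first_session_meeting` at the same threshold.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    run = 0
    for s in series.sessions:
        if s.score >= threshold_fraction * s.max_score:
            run += 1
            if run >= consecutive:
                return s.session_index
        else:
            run = 0
    return None


def phase_trend(series: CaseSeries, phase: str) -> float:
    """Descriptive OLS slope within one phase (score units per session)."""
    t, y = phase_slice(series, phase)
    if t.size < 2:
        raise ValueError(f"phase {phase!r} has fewer than 2 sessions")
    return fit_baseline_trend(t, y).slope


def _phase_descriptives(series: CaseSeries) -> dict:
    out = {}
    for phase in series.phases_present():
        t, y = phase_slice(series, phase)
        out[phase] = {
            "n": int(t.size),
            "mean": float(np.mean(y)),
            "sd": float(np.std(y, ddof=1)) if t.size > 1 else 0.0,
            "min": float(np.min(y)),
            "max": float(np.max(y)),
            "first_session": int(t[0]),
            "last_session": int(t[-1]),
        }
    return out


@dataclass(frozen=True)
class AnalysisReport:
    """Full per-case analysis; serializes deterministically to JSON/Markdown."""

    case_id: str
    design: str
    direction: str
    phases_compared: tuple[str, str]
    descriptives: dict
    scatter: list  # (session_index, score, phase, context)
    selection: MethodSelection
    headline_method: str
    headline_estimate: float
    band: InterpretationBand
    effect_sizes: dict
    parametric: Optional[dict]
    milestones: dict
    caveats: list

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phases_compared"] = list(d["phases_compared"])
        return d

    def to_json(self) -> str:
        def _plain(o):
            if isinstance(o, np.bool_):
                return bool(o)
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o).__name__}")

        return json.dumps(self.to_dict(), sort_keys=True, indent=2, default=_plain)

    def to_markdown(self) -> str:
        lines = [
            f"# Analysis report: {self.case_id}",
            "",
            f"Design: {self.design}; phases compared: "
            f"{self.phases_compared[0]} vs {self.phases_compared[1]}; "
            f"improvement direction: {self.direction}.",
            "",
            "## Descriptives",
            "",
            "| phase | n | mean | sd | min | max |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        for phase, st in self.descriptives.items():
            lines.append(
                f"| {phase} | {st['n']} | {st['mean']:.2f} | {st['sd']:.2f} "
                f"| {st['min']:.0f} | {st['max']:.0f} |"
            )
        lines += [
            "",
            "## Effect size",
            "",
            f"Selected method: **{self.headline_method}** "
            f"(rule {self.selection.rule_id}).",
            f"Headline estimate: **{self.headline_estimate:.4g}** — "
            f"band **{self.band.band}** "
            f"(gauge position {self.band.gauge_position:.2f}).",
            "",
            "All computed indices: "
            + ", ".join(f"{k} = {v:.4g}" for k, v in sorted(self.effect_sizes.items())),
        ]
        if self.parametric is not None:
            pm = self.parametric
            lines += [
                "",
                "## Detrended regression",
                "",
                f"c1 (level) = {pm['c1']:.4g}, c2 (slope) = {pm['c2']:.4g}, "
                f"R² = {pm['r_squared']:.4g}, "
                f"F({pm['df'][0]}, {pm['df'][1]}) = {pm['f_stat']:.4g}, "
                f"p = {pm['p_value']:.4g}, r = {pm['r']:.4g}; "
                f"cov(P, d) = {pm['cov_value']:.4g} "
                f"(assumption {'met' if pm['cov_assumption_met'] else 'NOT met'}).",
            ]
        if self.milestones:
            lines += ["", "## Milestones", ""]
            for k, v in sorted(self.milestones.items()):
                lines.append(f"- {k}: {'none' if v is None else f'session {v}'}")
        if self.caveats:
            lines += ["", "## Caveats", ""]
            for c in self.caveats:
                lines.append(f"- {c}")
        return "\n".join(lines) + "\n"


def build_report(series: CaseSeries, config: Optional[ReportConfig] = None) -> AnalysisReport:
    """Assemble the full analysis for one case; deterministic given inputs.

    All applicable non-overlap indices and (when identifiable) the
    parametric regression are computed; the selector's choice — or the
    method forced in ``config.method`` — headlines the report.
    """
    config = config or ReportConfig()
    problems = validate_series(series)
    if problems:
        raise ValueError("invalid series: " + "; ".join(v.message for v in problems[:5]))
    pa, pb = config.phases
    ta, ya = phase_slice(series, pa)
    tb, yb = phase_slice(series, pb)
    n_A, n_B = int(ta.size), int(tb.size)

    caveats = [f"Improvement direction assumed: {config.direction}."]

    parametric_dict: Optional[dict] = None
    param_result: Optional[ParametricResult] = None
    flags = AssumptionFlags(False, False, False)
    if n_A >= 2:
        trend = fit_baseline_trend(ta, ya)
        ds = detrend(series, trend, config.phases)
        cov_flag, _cov = check_covariance_assumption(ds, config.direction)
        flags = AssumptionFlags(
            baseline_time_variance_positive=True,
            baseline_trend_nonzero=bool(abs(trend.slope) > 1e-12),
            cov_assumption_met=bool(cov_flag),
        )
        if n_B >= 2 and n_A + n_B >= 5:
            param_result = analyze_parametric(
                series, config.phases, config.direction, config.alpha
            )
            parametric_dict = {
                "c0": param_result.c0,
                "c1": param_result.c1,
                "c2": param_result.c2,
                "r_squared": param_result.r_squared,
                "f_stat": param_result.f_stat,
                "df": list(param_result.df),
                "p_value": param_result.p_value,
                "r": param_result.r,
                "exact_fit": param_result.exact_fit,
                "cov_value": param_result.cov_value,
                "cov_assumption_met": param_result.cov_assumption_met,
            }

    selection = select_method(n_A, n_B, flags)
    A, B = list(ya), list(yb)
    effect_sizes = {
        "NAP": no.nap(A, B, config.direction).estimate,
        "PND": no.pnd(A, B, config.direction).estimate,
        "PEM": no.pem(A, B, config.direction).estimate,
        "TAU_AB": no.tau_ab(A, B, config.direction).estimate,
    }
    if n_A >= 2:
        tu = no.tau_u(A, B, config.direction)
        effect_sizes["TAU_U"] = tu.estimate
        if tu.out_of_range:
            caveats.append(
                "Tau-U exceeded [-1, 1] (baseline trend opposes the "
                "intervention); reported unclipped."
            )

    method = selection.method if config.method == "auto" else config.method
    if method == "parametric" and param_result is None:
        # forced parametric on unidentifiable data is a hard error; the
        # auto path can only land here if flags lied, which select_method's
        # preconditions exclude
        raise ValueError("parametric analysis not identifiable for this series")
    if method == "parametric":
        headline_method_key = "PARAMETRIC_R"
        headline_estimate = param_result.r
        caveats.append(ANTICONSERVATISM_CAVEAT)
        if not param_result.cov_assumption_met:
            caveats.append(
                "Covariance assumption cov(P, d) > 0 NOT met; the detrended "
                "regression may be misleading for this series."
            )
    else:
        headline_method_key = method.upper()
        headline_estimate = effect_sizes[headline_method_key]
    if config.method == "auto" and selection.method != "parametric" and not flags.cov_assumption_met:
        caveats.append(
            "Parametric path not selected: covariance assumption failed or "
            "phases too short (rule " + selection.rule_id + ")."
        )

    band = interpret(headline_method_key, headline_estimate, config.band_tables)

    milestones = {
        "first_positive_score": first_session_meeting(series, score_positive),
        "mastery": detect_mastery(
            series, config.mastery_threshold, config.mastery_consecutive
        ),
        "first_max_score": first_session_meeting(series, score_is_max),
    }

    scatter = [
        [s.session_index, s.score, s.phase, s.context] for s in series.sessions
    ]

    return AnalysisReport(
        case_id=series.case_id,
        design=series.design,
        direction=config.direction,
        phases_compared=config.phases,
        descriptives=_phase_descriptives(series),
        scatter=scatter,
        selection=selection,
        headline_method=method,
        headline_estimate=float(headline_estimate),
        band=band,
        effect_sizes={k: float(v) for k, v in effect_sizes.items()},
        parametric=parametric_dict,
        milestones=milestones,
        caveats=caveats,
    )
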