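"""Domain model for single-case experimental design (SCED) data.

The unit of analysis is a :class:`CaseSeries`: one subject, one target
behavior, and an ordered list of observation sessions labelled with study
phases.  Phases follow the AB(G) convention: a baseline phase ``A`` with no
intervention, an intervention phase ``B``, and an optional generalization
phase ``G`` recorded in a different context (typically at home by carers).

Session indexing is 1-based and *global* across phases: a 5-session baseline
followed by 30 training sessions occupies indices 1..35, and a subsequent
generalization phase continues at 36.  Milestones ("the first correct
response in session 8") are counted on this global axis, and the parametric
analysis uses the global index as its time regressor, which assumes sessions
are uniformly spaced — gaps must be re-indexed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

PHASES = ("A", "B", "G")
CONTEXTS = ("clinic", "home", "school", "other")

__all__ = [
    "PHASES",
    "CONTEXTS",
    "TargetBehavior",
    "ObservationSession",
    "CaseSeries",
    "Violation",
    "validate_series",
    "phase_slice",
]


@dataclass(frozen=True)
class TargetBehavior:
    """Operational definition of the behavior under observation.

    ``name`` is a short label; ``operational_definition`` states, in
    observable terms, what counts as an occurrence; ``place`` and
    ``setting`` record where and under which conditions observation happens.
    """

    name: str
    operational_definition: str
    place: str = ""
    setting: str = ""


@dataclass(frozen=True)
class ObservationSession:
    """One observation session: a bounded count score with metadata.

    ``score`` is the number of correct responses out of ``max_score``
    opportunities (0-50 in the mand-training case studies).  ``context``
    records the observation setting, ``observer`` who collected the data,
    and ``date`` an optional ISO-8601 date string.
    """

    session_index: int
    phase: str
    score: int
    max_score: int = 50
    context: str = "clinic"
    observer: str = ""
    date: Optional[str] = None


@dataclass(frozen=True)
class CaseSeries:
    """Ordered per-session scores with phase labels for one subject/behavior."""

    case_id: str
    sessions: tuple[ObservationSession, ...]
    behavior: Optional[TargetBehavior] = None
    design: str = "AB"

    def __post_init__(self) -> None:
        if not isinstance(self.sessions, tuple):
            object.__setattr__(self, "sessions", tuple(self.sessions))

    def phases_present(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.sessions:
            if s.phase not in seen:
                seen.append(s.phase)
        return tuple(seen)

    def n_in_phase(self, phase: str) -> int:
        return sum(1 for s in self.sessions if s.phase == phase)

    def with_sessions(self, sessions: Iterable[ObservationSession]) -> "CaseSeries":
        return replace(self, sessions=tuple(sessions))


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_series`.

    Violations are data, not exceptions: a validator reports every problem
    it finds, with the session index it concerns (or ``None`` for
    series-level rules) and a stable rule id.
    """

    rule_id: str
    message: str
    session_index: Optional[int] = None


def validate_series(series: CaseSeries) -> list[Violation]:
    """Check every invariant of a :class:`CaseSeries`; empty list = valid.

    Rules checked: behavior metadata completeness (when present), score
    bounds (0 <= score <= max_score), positive max_score, integer scores,
    known phase and context labels, strictly consecutive 1-based session
    indices, and the A -> B -> G phase ordering with no interleaving.
    """
    out: list[Violation] = []
    if series.behavior is not None:
        if not series.behavior.name:
            out.append(Violation("behavior-name-empty", "behavior name is empty"))
        if not series.behavior.operational_definition:
            out.append(
                Violation(
                    "behavior-definition-empty",
                    "behavior operational definition is empty",
                )
            )
    if not series.case_id:
        out.append(Violation("case-id-empty", "case_id is empty"))

    expected = 1
    last_phase_rank = -1
    for s in series.sessions:
        idx = s.session_index
        if idx != expected:
            out.append(
                Violation(
                    "index-not-consecutive",
                    f"session_index {idx} found where {expected} was expected",
                    idx,
                )
            )
            expected = idx + 1
        else:
            expected += 1
        if s.phase not in PHASES:
            out.append(
                Violation("phase-unknown", f"unknown phase label {s.phase!r}", idx)
            )
        else:
            rank = PHASES.index(s.phase)
            if rank < last_phase_rank:
                out.append(
                    Violation(
                        "phase-order",
                        f"phase {s.phase!r} appears after "
                        f"{PHASES[last_phase_rank]!r}; phases must run A, B, G",
                        idx,
                    )
                )
            last_phase_rank = max(last_phase_rank, rank)
        if not isinstance(s.score, (int, np.integer)):
            out.append(
                Violation("score-not-integer", f"score {s.score!r} is not an integer", idx)
            )
            continue
        if s.max_score <= 0:
            out.append(
                Violation("max-score-not-positive", f"max_score {s.max_score} <= 0", idx)
            )
        if not (0 <= s.score <= s.max_score):
            out.append(
                Violation(
                    "score-out-of-range",
                    f"score {s.score} outside [0, {s.max_score}]",
                    idx,
                )
            )
        if s.context not in CONTEXTS:
            out.append(
                Violation("context-unknown", f"unknown context {s.context!r}", idx)
            )
    return out


def phase_slice(series: CaseSeries, phase: str) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(t, y)`` vectors for one phase, keeping global session indices.

    Raises ``ValueError`` naming the label when the phase is absent from the
    series.  Concatenating the A, B, G slices in order reconstructs the full
    session list (the slices partition the series).
    """
    t = [s.session_index for s in series.sessions if s.phase == phase]
    if not t:
        raise ValueError(f"phase {phase!r} not present in series {series.case_id!r}")
    y = [s.score for s in series.sessions if s.phase == phase]
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)
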