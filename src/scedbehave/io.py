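"""Readers and writers: session CSV, simulation config, report files.

The canonical session CSV has the header

    case_id,session_index,phase,score,max_score,context,observer,date

one row per observation session, UTF-8, LF line endings, RFC-4180 quoting,
ISO-8601 dates.  Foreign CSV dialects are adapted through a
:class:`ColumnMapping`: a rename table from the canonical field names to
source column names plus a phase-label dictionary (e.g. "baseline" -> A,
"training" -> B, "generalization" -> G), so arbitrary source vocabularies
can be ingested without touching the reader.

Scores must be integers (the dependent variable is a count of correct
responses); fractional scores are rejected with the offending row number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .engine import AnalysisReport
from .model import CaseSeries, ObservationSession, validate_series
from .simulate import SimConfig

CANONICAL_COLUMNS = (
    "case_id",
    "session_index",
    "phase",
    "score",
    "max_score",
    "context",
    "observer",
    "date",
)
REQUIRED_COLUMNS = ("case_id", "session_index", "phase", "score")

__all__ = [
    "CANONICAL_COLUMNS",
    "ColumnMapping",
    "SessionCsvError",
    "read_sessions_csv",
    "write_sessions_csv",
    "write_report",
    "read_sim_config",
]


class SessionCsvError(ValueError):
    """A parse or consistency failure in a session CSV, with row context."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


@dataclass(frozen=True)
class ColumnMapping:
    """Adapter from a source CSV dialect to the canonical schema.

    ``columns`` maps canonical field names to source column names (fields
    absent from the source may be omitted, except the required four);
    ``phase_labels`` maps source phase vocabulary to {A, B, G}.
    """

    columns: dict = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )
    phase_labels: dict = field(
        default_factory=lambda: {"A": "A", "B": "B", "G": "G"}
    )

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.columns]
        if missing:
            raise ValueError(f"mapping missing required fields: {missing}")

    @classmethod
    def canonical(cls) -> "ColumnMapping":
        return cls()

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ColumnMapping":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            columns=doc.get("columns", {c: c for c in CANONICAL_COLUMNS}),
            phase_labels=doc.get("phase_labels", {"A": "A", "B": "B", "G": "G"}),
        )


def _parse_int(value: str, what: str, row: int) -> int:
    s = str(value).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        f = float(s)
    except ValueError:
        raise SessionCsvError(f"{what} {value!r} is not an integer", row) from None
    if f != int(f):
        raise SessionCsvError(f"{what} {value!r} is fractional; scores are counts", row)
    return int(f)


def read_sessions_csv(
    path: Union[str, Path], mapping: Optional[ColumnMapping] = None
) -> list[CaseSeries]:
    """Read a session CSV into validated :class:`CaseSeries`, one per case.

    Sessions are sorted by session index within each case; duplicate
    (case_id, session_index) pairs, unmapped columns and non-integer scores
    raise :class:`SessionCsvError` naming the offending row.  Series whose
    invariants fail raise with the collected violations.
    """
    mapping = mapping or ColumnMapping.canonical()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canon in REQUIRED_COLUMNS:
        src = mapping.columns[canon]
        if src not in df.columns:
            raise SessionCsvError(f"mapped column {src!r} (for {canon}) not in file")

    def col(canon: str, row_i: int, default: str = "") -> str:
        src = mapping.columns.get(canon)
        if src is None or src not in df.columns:
            return default
        return str(df.iloc[row_i][src])

    by_case: dict[str, list[ObservationSession]] = {}
    seen: set[tuple[str, int]] = set()
    for i in range(len(df)):
        row_no = i + 2  # header is row 1
        case_id = col("case_id", i)
        idx = _parse_int(col("session_index", i), "session_index", row_no)
        raw_phase = col("phase", i)
        phase = mapping.phase_labels.get(raw_phase, raw_phase)
        score = _parse_int(col("score", i), "score", row_no)
        max_score = _parse_int(col("max_score", i, "50") or "50", "max_score", row_no)
        if (case_id, idx) in seen:
            raise SessionCsvError(
                f"duplicate session_index {idx} for case {case_id!r}", row_no
            )
        seen.add((case_id, idx))
        date = col("date", i) or None
        by_case.setdefault(case_id, []).append(
            ObservationSession(
                session_index=idx,
                phase=phase,
                score=score,
                max_score=max_score,
                context=col("context", i, "clinic") or "clinic",
                observer=col("observer", i),
                date=date,
            )
        )

    out = []
    for case_id, sessions in by_case.items():
        sessions.sort(key=lambda s: s.session_index)
        series = CaseSeries(case_id=case_id, sessions=tuple(sessions))
        problems = validate_series(series)
        if problems:
            raise SessionCsvError(
                f"case {case_id!r} invalid: "
                + "; ".join(v.message for v in problems[:5])
            )
        out.append(series)
    return out


def write_sessions_csv(series_list: Sequence[CaseSeries], path: Union[str, Path]) -> None:
    """Write series to the canonical CSV; ``read(write(x)) == x`` on the
    session-level fields."""
    rows = []
    for series in series_list:
        for s in series.sessions:
            rows.append(
                {
                    "case_id": series.case_id,
                    "session_index": s.session_index,
                    "phase": s.phase,
                    "score": s.score,
                    "max_score": s.max_score,
                    "context": s.context,
                    "observer": s.observer,
                    "date": s.date if s.date is not None else "",
                }
            )
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def write_report(report: AnalysisReport, path: Union[str, Path], format: str = "json") -> None:
    """Serialize a report; JSON output is byte-stable for identical input."""
    path = Path(path)
    if format == "json":
        path.write_text(report.to_json() + "\n", encoding="utf-8")
    elif format == "markdown":
        path.write_text(report.to_markdown(), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_sim_config(path: Union[str, Path]) -> SimConfig:
    """Load a :class:`SimConfig` from YAML or JSON (YAML parses both)."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = set(SimConfig.__dataclass_fields__)
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {unknown}")
    cfg = SimConfig(**doc)
    cfg.validate()
    return cfg
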