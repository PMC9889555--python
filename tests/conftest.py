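import numpy as np
import pytest

from scedbehave.model import CaseSeries, ObservationSession, TargetBehavior


def make_series(scores_by_phase, case_id="case", max_score=50, contexts=None):
    """Build a CaseSeries from {"A": [...], "B": [...], ...} with global indices."""
    sessions = []
    t = 1
    for phase in ("A", "B", "G"):
        if phase not in scores_by_phase:
            continue
        ctx = (contexts or {}).get(phase, "home" if phase == "G" else "clinic")
        for y in scores_by_phase[phase]:
            sessions.append(
                ObservationSession(t, phase, int(y), max_score, context=ctx)
            )
            t += 1
    return CaseSeries(
        case_id=case_id,
        sessions=tuple(sessions),
        behavior=TargetBehavior("mand", "correct request within 5 s", "clinic", "DTT"),
    )


@pytest.fixture
def series_5a30b():
    """Case-study-shaped series: 5-session zero baseline, 30 training sessions."""
    rng = np.random.default_rng(7)
    b = np.clip(np.round(50 / (1 + np.exp(-0.45 * (np.arange(6, 36) - 16)))
                         + rng.normal(0, 2, 30)), 0, 50).astype(int)
    return make_series({"A": [0] * 5, "B": list(b)})


@pytest.fixture
def series_with_g(series_5a30b):
    g = [20, 24, 29, 31, 35, 38, 40, 43, 45, 46]
    sessions = list(series_5a30b.sessions)
    t = sessions[-1].session_index
    for i, y in enumerate(g, 1):
        sessions.append(ObservationSession(t + i, "G", y, 50, context="home"))
    return series_5a30b.with_sessions(sessions)
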