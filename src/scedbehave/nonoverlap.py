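"""Non-overlap effect-size indices for two-phase (AB) comparisons.

These are the distribution-free effect sizes standard in single-case
research: NAP (non-overlap of all pairs), PND (percentage of
non-overlapping data), PEM (percentage of data exceeding the baseline
median), Tau-AB (Kendall-type cross-phase dominance) and Tau-U (Tau-AB with
a baseline-trend correction).  All operate on the raw phase score vectors
and are invariant under any strictly monotone transform of the scores.

Conventions: ties count 0.5 toward improvement in NAP and PEM, which makes
``NAP(A, A) = 0.5`` exact; Tau-AB satisfies ``Tau = 2*NAP - 1``.  The
``improvement_direction`` argument states the therapeutic goal — with
``"decrease"`` all comparisons are mirrored.  Tau-U (the baseline-trend
corrected variant, ``(S_AB - S_AA) / (n_A * n_B)``) can exceed [-1, 1]
when the baseline trend opposes the intervention; it is reported unclipped
with an ``out_of_range`` flag.

:func:`pairwise_oracle` enumerates every cross-phase pair explicitly and
exists as an independent check on the vectorized implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

DIRECTIONS = ("increase", "decrease")

__all__ = [
    "NonoverlapResult",
    "nap",
    "pnd",
    "pem",
    "tau_ab",
    "tau_u",
    "pairwise_oracle",
]


@dataclass(frozen=True)
class NonoverlapResult:
    method: str  # NAP | PND | PEM | TAU_AB | TAU_U
    estimate: float
    n_A: int
    n_B: int
    improvement_direction: str = "increase"
    out_of_range: bool = False


def _oriented(A: Sequence[float], B: Sequence[float], direction: str):
    """Return arrays oriented so that 'improved' always means b > a."""
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown improvement direction {direction!r}")
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both phases must contain at least one observation")
    if direction == "decrease":
        a, b = -a, -b
    return a, b


def nap(A: Sequence[float], B: Sequence[float], direction: str = "increase") -> NonoverlapResult:
    """Non-overlap of all pairs: P(B improved over A) with 0.5 tie weight.

    Equals the Mann-Whitney U statistic of the intervention phase divided
    by the number of cross-phase pairs, so it lives on [0, 1] with 0.5 at
    chance level.
    """
    a, b = _oriented(A, B, direction)
    u_b = stats.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic").statistic
    est = float(u_b) / (a.size * b.size)
    return NonoverlapResult("NAP", est, a.size, b.size, direction)


def pnd(A: Sequence[float], B: Sequence[float], direction: str = "increase") -> NonoverlapResult:
    """Percentage of intervention points strictly exceeding the baseline extreme."""
    a, b = _oriented(A, B, direction)
    est = 100.0 * float(np.mean(b > a.max()))
    return NonoverlapResult("PND", est, a.size, b.size, direction)


def pem(A: Sequence[float], B: Sequence[float], direction: str = "increase") -> NonoverlapResult:
    """Percentage of intervention points exceeding the baseline median (ties 0.5)."""
    a, b = _oriented(A, B, direction)
    med = float(np.median(a))
    est = 100.0 * float(np.sum(b > med) + 0.5 * np.sum(b == med)) / b.size
    return NonoverlapResult("PEM", est, a.size, b.size, direction)


def tau_ab(A: Sequence[float], B: Sequence[float], direction: str = "increase") -> NonoverlapResult:
    """Cross-phase dominance: (improved - deteriorated pairs) / all pairs."""
    a, b = _oriented(A, B, direction)
    diff = np.sign(b[None, :] - a[:, None])
    est = float(diff.sum()) / (a.size * b.size)
    return NonoverlapResult("TAU_AB", est, a.size, b.size, direction)


def tau_u(A: Sequence[float], B: Sequence[float], direction: str = "increase") -> NonoverlapResult:
    """Tau-AB corrected for baseline trend: ``(S_AB - S_AA) / (n_A * n_B)``.

    ``S_AB`` is the improved-minus-deteriorated count over cross-phase
    pairs; ``S_AA`` the same over time-ordered within-baseline pairs, so a
    baseline already drifting toward the goal is discounted.  Requires
    ``n_A >= 2`` (otherwise there are no within-baseline pairs).  The
    estimate may leave [-1, 1]; it is reported unclipped with
    ``out_of_range`` set.
    """
    a, b = _oriented(A, B, direction)
    if a.size < 2:
        raise ValueError("tau_u needs n_A >= 2 (no within-baseline pairs otherwise)")
    s_ab = float(np.sign(b[None, :] - a[:, None]).sum())
    i, j = np.triu_indices(a.size, k=1)
    s_aa = float(np.sign(a[j] - a[i]).sum())
    est = (s_ab - s_aa) / (a.size * b.size)
    return NonoverlapResult(
        "TAU_U", est, a.size, b.size, direction, out_of_range=not -1.0 <= est <= 1.0
    )


def pairwise_oracle(
    A: Sequence[float], B: Sequence[float], direction: str = "increase"
) -> list[tuple[int, int, str]]:
    """Exhaustively classify every cross-phase pair.

    Returns ``(i, j, outcome)`` for baseline point ``i`` vs intervention
    point ``j``, outcome in {"improved", "tied", "deteriorated"}.  NAP and
    Tau-AB recomputed from this table must match the vectorized
    implementations exactly.
    """
    a, b = _oriented(A, B, direction)
    table = []
    for i, av in enumerate(a):
        for j, bv in enumerate(b):
            if bv > av:
                outcome = "improved"
            elif bv < av:
                outcome = "deteriorated"
            else:
                outcome = "tied"
            table.append((i, j, outcome))
    return table
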