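"""Synthetic SCED generator and Monte-Carlo validation harnesses.

The generator emulates the statistical structure of a discrete-trial
mand-training study: each session offers ``m`` trials (default 50 — ten
opportunities for each of five target items), the session score is the
number of correct responses, baseline responding is at probability ``p0``
(default 0: an all-zero baseline), and acquisition during intervention
follows a logistic learning curve

    p_t = p_max / (1 + exp(-k * (t - t0)))

over the global session index t, with per-session scores drawn
``Binomial(m, p_t)``.  A generalization phase uses the same curve family
with its own parameters (a later start in a new context, recorded as
``home``).  Sessions are conditionally independent given p_t; serial
correlation is not modeled (an AR(1) hook exists in the config but is not
implemented).

Defaults mirror the case-study design: 5 baseline, 30 training and 10
generalization sessions; the default curve (p_max 0.95, k 0.45, t0 16)
yields first correct responses around session 7-8, ~80% correct by session
20 and stable performance after session 30.

:func:`run_mc` repeats simulate-then-analyze to measure type-I error rate,
power and estimate distributions.  Per-repetition seeds derive from the
master seed as ``SeedSequence([master_seed, rep_index])``, so any single
repetition is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Optional

import numpy as np

from .model import CaseSeries, ObservationSession, TargetBehavior

__all__ = ["SimConfig", "MCResult", "simulate_case", "null_series", "run_mc", "rep_seed"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic acquisition model."""

    trials_per_session: int = 50
    n_A: int = 5
    n_B: int = 30
    n_G: int = 10
    p0: float = 0.0  # baseline success probability
    curve: str = "logistic"  # logistic | linear
    p_max: float = 0.95
    k: float = 0.45  # logistic rate (1/sessions)
    t0: float = 16.0  # logistic midpoint, global session index
    g_p_max: float = 0.9
    g_k: float = 0.5
    g_t0_offset: float = 4.0  # generalization midpoint, sessions after G start
    ar1_rho: float = 0.0  # serial-correlation hook; only 0.0 implemented
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for name in ("p0", "p_max", "g_p_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name}={v} outside [0, 1]")
        if self.trials_per_session < 1:
            bad.append("trials_per_session < 1")
        for name in ("n_A", "n_B", "n_G"):
            if getattr(self, name) < 0:
                bad.append(f"{name} < 0")
        if self.k <= 0 or self.g_k <= 0:
            bad.append("logistic rate must be > 0")
        if self.curve not in ("logistic", "linear"):
            bad.append(f"unknown curve kind {self.curve!r}")
        if bad:
            raise ValueError("invalid SimConfig: " + "; ".join(bad))
        if self.ar1_rho != 0.0:
            raise NotImplementedError("AR(1) serial correlation is not implemented")


def _curve_p(cfg: SimConfig, t: np.ndarray, start: float, p_max: float, k: float, t0: float) -> np.ndarray:
    if cfg.curve == "logistic":
        return p_max / (1.0 + np.exp(-k * (t - t0)))
    # linear ramp from 0 at phase start to p_max at the phase's last session
    span = max(float(t[-1] - start), 1.0)
    return p_max * np.clip((t - start) / span, 0.0, 1.0)


_SIM_BEHAVIOR = TargetBehavior(
    name="simulated mand",
    operational_definition="synthetic correct-response count per session",
    place="simulation",
    setting="simulation",
)


def simulate_case(config: SimConfig) -> CaseSeries:
    """Draw one synthetic case series; identical config (incl. seed) gives
    identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.trials_per_session
    sessions: list[ObservationSession] = []
    t = 1
    for _ in range(config.n_A):
        score = int(rng.binomial(m, config.p0))
        sessions.append(ObservationSession(t, "A", score, m, context="clinic"))
        t += 1
    b_t = np.arange(t, t + config.n_B, dtype=float)
    if config.n_B:
        p_b = np.clip(
            _curve_p(config, b_t, float(b_t[0]), config.p_max, config.k, config.t0),
            0.0,
            1.0,
        )
        for tt, p in zip(b_t, p_b):
            sessions.append(
                ObservationSession(int(tt), "B", int(rng.binomial(m, p)), m, context="clinic")
            )
        t += config.n_B
    g_t = np.arange(t, t + config.n_G, dtype=float)
    if config.n_G:
        g_t0 = float(g_t[0]) + config.g_t0_offset
        p_g = np.clip(
            _curve_p(config, g_t, float(g_t[0]), config.g_p_max, config.g_k, g_t0),
            0.0,
            1.0,
        )
        for tt, p in zip(g_t, p_g):
            sessions.append(
                ObservationSession(int(tt), "G", int(rng.binomial(m, p)), m, context="home")
            )
    return CaseSeries(
        case_id=f"sim-{config.seed}", sessions=tuple(sessions), behavior=_SIM_BEHAVIOR
    )


def null_series(config: SimConfig) -> CaseSeries:
    """A no-effect case: every phase shares the constant probability ``p0``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.trials_per_session
    sessions = []
    t = 1
    for phase, n, ctx in (("A", config.n_A, "clinic"), ("B", config.n_B, "clinic"), ("G", config.n_G, "home")):
        for _ in range(n):
            sessions.append(
                ObservationSession(t, phase, int(rng.binomial(m, config.p0)), m, context=ctx)
            )
            t += 1
    return CaseSeries(
        case_id=f"null-{config.seed}", sessions=tuple(sessions), behavior=_SIM_BEHAVIOR
    )


def rep_seed(master_seed: int, rep_index: int) -> int:
    """Fixed master-seed -> per-repetition seed derivation (documented so a
    single repetition can be reproduced in isolation)."""
    ss = np.random.SeedSequence([int(master_seed), int(rep_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class MCResult:
    n_reps: int
    alpha: float
    rejection_rate: float
    n_rejected: int
    n_analyzed: int
    n_degenerate: int
    summaries: dict  # per-quantity {mean, sd, q05, q50, q95}

    def to_dict(self) -> dict:
        return asdict(self)


def _summary(values: list[float]) -> dict:
    if not values:
        return {"mean": None, "sd": None, "q05": None, "q50": None, "q95": None}
    a = np.asarray(values, dtype=float)
    return {
        "mean": float(a.mean()),
        "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "q05": float(np.quantile(a, 0.05)),
        "q50": float(np.quantile(a, 0.50)),
        "q95": float(np.quantile(a, 0.95)),
    }


def run_mc(
    analysis: Callable[[CaseSeries], object],
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    simulator: Optional[Callable[[SimConfig], CaseSeries]] = None,
    master_seed: Optional[int] = None,
) -> MCResult:
    """Repeat simulate-then-analyze and summarize the outcomes.

    ``analysis`` maps a :class:`CaseSeries` to any object with a
    ``p_value`` attribute (``c1``, ``c2``, ``r`` and ``r_squared`` are
    summarized when present).  ``simulator`` defaults to :func:`simulate_case`; pass
    :func:`null_series` for type-I studies.  Repetition i runs on
    ``rep_seed(master_seed, i)``; ``master_seed`` defaults to
    ``config.seed``.  Degenerate repetitions — where ``analysis`` raises,
    e.g. a zero-variance baseline breaking the parametric path — are
    counted, not silently dropped; they contribute to ``n_degenerate`` and
    are excluded from the rejection rate's denominator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    simulator = simulator or simulate_case
    master = config.seed if master_seed is None else master_seed
    rejected = 0
    analyzed = 0
    degenerate = 0
    collected: dict[str, list[float]] = {"c1": [], "c2": [], "r": [], "r_squared": []}
    for i in range(n_reps):
        series = simulator(replace(config, seed=rep_seed(master, i)))
        try:
            res = analysis(series)
        except (ValueError, np.linalg.LinAlgError):
            degenerate += 1
            continue
        analyzed += 1
        if getattr(res, "p_value", 1.0) < alpha:
            rejected += 1
        for name in collected:
            v = getattr(res, name, None)
            if v is not None:
                collected[name].append(float(v))
    rate = rejected / analyzed if analyzed else float("nan")
    return MCResult(
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=rate,
        n_rejected=rejected,
        n_analyzed=analyzed,
        n_degenerate=degenerate,
        summaries={k: _summary(v) for k, v in collected.items()},
    )
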