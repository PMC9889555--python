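"""Generic plots: phase scatter and effect-size gauge.

Deliberately plain matplotlib — the report carries the data; these are
convenience renderings, not pixel-specified graphics.
"""

from __future__ import annotations

import numpy as np

from .engine import AnalysisReport
from .model import CaseSeries

_PHASE_COLORS = {"A": "tab:gray", "B": "tab:blue", "G": "tab:green"}


def plot_case(series: CaseSeries, ax=None):
    """Scatter of session scores, one color per phase, phase boundaries marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for phase in series.phases_present():
        pts = [(s.session_index, s.score) for s in series.sessions if s.phase == phase]
        t, y = zip(*pts)
        ax.scatter(t, y, s=18, color=_PHASE_COLORS.get(phase, "k"), label=phase)
        ax.axvline(t[0] - 0.5, color="k", lw=0.5, ls="--")
    ax.set_xlabel("session")
    ax.set_ylabel("score")
    ax.set_title(series.case_id)
    ax.legend(title="phase")
    return ax


def plot_gauge(report: AnalysisReport, ax=None):
    """Semi-circular gauge for the headline effect size and its band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"aspect": "equal"}, figsize=(4, 2.5))
    theta = np.linspace(np.pi, 0, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="0.7", lw=8, solid_capstyle="round")
    pos = report.band.gauge_position
    ang = np.pi * (1 - pos)
    ax.annotate(
        "",
        xy=(0.9 * np.cos(ang), 0.9 * np.sin(ang)),
        xytext=(0, 0),
        arrowprops={"arrowstyle": "-|>", "color": "tab:red", "lw": 2},
    )
    ax.text(
        0,
        -0.15,
        f"{report.headline_method}: {report.headline_estimate:.3g} ({report.band.band})",
        ha="center",
    )
    ax.set_axis_off()
    return ax
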