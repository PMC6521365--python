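"""Diagnostic figures: why was this participant flagged?

Two plot families mirror the communication artifacts of the evaluation
process: a scatter of the cohort on an outlier's two primary contributing
variables (with the flagged participant drawn as a crossed circle, and an
optional third variable as a colour gradient), and per-variable boxplots
overlaid with the univariate-MCD typical range and any highlighted cells.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are written to files

import matplotlib.pyplot as plt
import numpy as np

from .datasets import PreparedDataset
from .univariate import UnivariateResult

__all__ = ["contribution_scatter", "boxplot_with_ranges"]


def _crossed_circle(ax, x, y, size=130):
    ax.scatter([x], [y], s=size, facecolors="none", edgecolors="crimson",
               linewidths=1.6, zorder=5)
    ax.scatter([x], [y], marker="x", s=size * 0.55, color="crimson",
               linewidths=1.6, zorder=6)


def contribution_scatter(prepared: PreparedDataset, result, participant_id: str,
                         x: str | None = None, y: str | None = None,
                         z: str | None = None, path="scatter.png"):
    """Scatter the cohort on an outlier's two primary contributing variables.

    Defaults to the participant's top-2 contributions from ``result`` (an
    MCD or RPCA result); ``z`` adds a colour gradient for a third variable.
    The flagged participant is drawn as a crossed circle.  Raises if the
    participant is not flagged — pick variables explicitly for unflagged
    participants via a different participant or detector run.
    """
    i = prepared.ids.index(str(participant_id))
    flags = result.flags
    if not flags[i]:
        raise ValueError(
            f"participant {participant_id!r} is not flagged by this result; "
            "choose a flagged participant or specify variables from another run")
    if x is None or y is None:
        ranked = result.ranked_contributions(i, top=2)
        if len(ranked) < 2:
            raise ValueError(
                "fewer than two contributing variables; pass x= and y=")
        x = x or ranked[0][0]
        y = y or ranked[1][0]
    xi = prepared.variable_names.index(x)
    yi = prepared.variable_names.index(y)
    xv, yv = prepared.values[:, xi], prepared.values[:, yi]

    fig, ax = plt.subplots(figsize=(6, 5))
    if z is not None:
        zi = prepared.variable_names.index(z)
        sc = ax.scatter(xv, yv, c=prepared.values[:, zi], cmap="viridis",
                        s=28, alpha=0.85)
        fig.colorbar(sc, ax=ax, label=z)
    else:
        ax.scatter(xv, yv, s=28, color="steelblue", alpha=0.75)
    _crossed_circle(ax, xv[i], yv[i])
    state = "adjusted" if prepared.adjusted else "unadjusted"
    ax.set_xlabel(f"{x} ({state})")
    ax.set_ylabel(f"{y} ({state})")
    ax.set_title(f"{participant_id}: primary contributing variables")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def boxplot_with_ranges(x, variable: str = "x",
                        umcd_result: UnivariateResult | None = None,
                        highlight_indices=(), path="boxplot.png"):
    """Boxplot with the uMCD typical-value interval and highlighted cells.

    The uMCD interval is drawn as bracket-style markers beside the box; an
    excluded variable (zero robust variance) gets an annotation instead.
    Highlighted cells (e.g. values at which an error was identified) are
    crossed circles at their observed values.
    """
    x = np.asarray(x, dtype=float)
    fig, ax = plt.subplots(figsize=(3.6, 5))
    ax.boxplot([x], widths=0.45, positions=[1.0])
    if umcd_result is not None:
        if umcd_result.excluded:
            ax.annotate("uMCD interval omitted:\nzero robust variance",
                        xy=(0.98, 0.02), xycoords="axes fraction",
                        ha="right", fontsize=8, color="dimgray")
        else:
            for bound in (umcd_result.lower_bound, umcd_result.upper_bound):
                ax.plot([1.28, 1.34, 1.34, 1.28],
                        [bound, bound, bound, bound], color="darkorange")
            ax.plot([1.34, 1.34],
                    [umcd_result.lower_bound, umcd_result.upper_bound],
                    color="darkorange", linewidth=1.4,
                    label="uMCD typical range")
            ax.legend(loc="upper left", fontsize=8)
    for i in highlight_indices:
        _crossed_circle(ax, 1.0, x[int(i)], size=90)
    ax.set_xticks([1.0])
    ax.set_xticklabels([variable])
    ax.set_ylabel("standardized value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
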