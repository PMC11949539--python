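"""Panel figure: one panel per group, one prevalence curve per species.

Layout follows the field convention for sampling-effort plots: x-axis is
the number of samples k, y-axis the mean prevalence in percent. Each
species' stability point is marked with a dotted vertical line and its
integer value printed at the top of the panel in the species colour; the
estimated prevalence (1 decimal place) is printed next to the curve tail.
An insufficient sampling effort prints "na" at the top instead, with no
dotted line. Species coinciding at the same stability point share one
dotted line but all numbers are printed. A shared species legend sits at
the bottom of the figure.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.lines import Line2D

from .types import PrevalenceCurve, StabilityResult

__all__ = ["plot_panels", "format_prevalence"]


def format_prevalence(value: float, digits: int = 1) -> str:
    """Format a prevalence for display: fixed decimals, half away from zero."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "na"
    q = Decimal(1).scaleb(-digits)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _check_pairs(pairs) -> None:
    for curve, result in pairs:
        if curve is None or result is None:
            raise ValueError("every curve needs a matching stability result")
        if (curve.group, curve.species) != (result.group, result.species):
            raise ValueError(
                f"curve/result mismatch: {(curve.group, curve.species)} vs "
                f"{(result.group, result.species)}"
            )


def plot_panels(
    pairs: Sequence[tuple[PrevalenceCurve, StabilityResult]],
    path: str | Path | None = None,
    *,
    ncols: int = 3,
    panel_size: tuple[float, float] = (4.0, 3.0),
    dpi: int = 300,
    colors: Sequence[str] | None = None,
):
    """Render the panel figure; saves to ``path`` if given, returns the figure.

    Output format follows the file extension (png/svg/pdf).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("nothing to plot")
    _check_pairs(pairs)

    group_order = list(dict.fromkeys(c.group for c, _ in pairs))
    species_order = list(dict.fromkeys(c.species for c, _ in pairs))
    if colors is None:
        cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
        colors = [cycle[i % len(cycle)] for i in range(len(species_order))]
    color_of = dict(zip(species_order, colors))

    n_groups = len(group_order)
    ncols = min(ncols, n_groups)
    nrows = math.ceil(n_groups / ncols)
    fig, axes = plt.subplots(
        nrows,
        ncols,
        figsize=(panel_size[0] * ncols, panel_size[1] * nrows + 0.6),
        squeeze=False,
    )

    for gi, group in enumerate(group_order):
        ax = axes[gi // ncols][gi % ncols]
        gpairs = [(c, r) for c, r in pairs if c.group == group]
        drawn_lines: set[int] = set()
        label_stack: dict[int, int] = {}
        top_slots = 0
        for curve, result in gpairs:
            color = color_of[curve.species]
            ks = range(1, curve.k_max + 1)
            ax.plot(ks, curve.means, color=color, lw=1.2)
            if result.stability_point is None:
                ax.text(
                    0.98 - 0.08 * top_slots,
                    1.02,
                    "na",
                    transform=ax.transAxes,
                    ha="right",
                    va="bottom",
                    color=color,
                    fontsize=9,
                )
                top_slots += 1
            else:
                k_star = result.stability_point
                if k_star not in drawn_lines:  # coincident points share one dotted line
                    ax.axvline(k_star, linestyle=":", color="0.4", lw=1.0)
                    drawn_lines.add(k_star)
                stack = label_stack.get(k_star, 0)
                label_stack[k_star] = stack + 1
                ax.text(
                    k_star,
                    1.02 + 0.07 * stack,
                    str(k_star),
                    transform=ax.get_xaxis_transform(),
                    ha="center",
                    va="bottom",
                    color=color,
                    fontsize=9,
                )
                ax.text(
                    curve.k_max * 1.01,
                    curve.means[-1],
                    format_prevalence(result.estimated_prevalence),
                    ha="left",
                    va="center",
                    color=color,
                    fontsize=9,
                )
        ax.set_title(group, fontsize=10, style="italic", pad=16)
        ax.set_xlabel("Number of samples")
        ax.set_ylabel("Mean prevalence (%)")
        ax.set_ylim(-2, 102)
        ax.margins(x=0.08)
    for gi in range(n_groups, nrows * ncols):
        axes[gi // ncols][gi % ncols].set_visible(False)

    handles = [
        Line2D([0], [0], color=color_of[s], lw=2, label=s) for s in species_order
    ]
    fig.legend(
        handles=handles,
        loc="lower center",
        ncol=min(len(handles), 3),
        frameon=False,
        fontsize=9,
    )
    fig.tight_layout(rect=(0, 0.06 + 0.02 * (len(species_order) > 3), 1, 1))
    if path is not None:
        fig.savefig(Path(path), dpi=dpi)
    return fig
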