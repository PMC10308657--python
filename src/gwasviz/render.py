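"""Render a PlotSpec with matplotlib.

The renderer consumes only the declarative spec — it adds no layout logic
of its own, so two identical specs always draw the same figure.  Output
formats (PNG/SVG/PDF) follow the file extension.
"""

from __future__ import annotations

import os

os.environ.setdefault("MPLBACKEND", "Agg")

import matplotlib

matplotlib.use(os.environ["MPLBACKEND"], force=False)

import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle
from matplotlib.ticker import FuncFormatter

from .plotspec import Panel, PlotSpec

_FONTFACE = {
    "plain": {"fontweight": "normal", "fontstyle": "normal"},
    "bold": {"fontweight": "bold", "fontstyle": "normal"},
    "italic": {"fontweight": "normal", "fontstyle": "italic"},
}

_LEGEND_LOC = {
    "top right": "upper right",
    "top left": "upper left",
    "bottom right": "lower right",
    "bottom left": "lower left",
}


def render(
    spec: PlotSpec,
    path: str | None = None,
    width: float = 10.0,
    height: float | None = None,
    dpi: int = 150,
):
    """Draw ``spec``; save to ``path`` when given, else return the Figure."""
    heights = [p.height for p in spec.panels]
    if height is None:
        height = 1.2 * sum(heights) + 0.8
    fig, axes = plt.subplots(
        len(spec.panels),
        1,
        figsize=(width, height),
        gridspec_kw={"height_ratios": heights},
        squeeze=False,
        constrained_layout=True,
    )
    for panel, ax in zip(spec.panels, axes[:, 0]):
        _draw_panel(panel, ax)
    if spec.title:
        fig.suptitle(spec.title)
    if spec.region_text:
        axes[0, 0].set_title(spec.region_text, fontsize=9, loc="right")
    if spec.legend:
        main_ax = axes[0, 0]
        for p, ax in zip(spec.panels, axes[:, 0]):
            if p.kind in ("main", "effect"):
                main_ax = ax
                break
        handles = [
            plt.Line2D([], [], marker="o", linestyle="", color=c, label=l)
            for l, c in spec.legend.entries
        ]
        main_ax.legend(
            handles=handles,
            loc=_LEGEND_LOC.get(spec.legend.position, "upper right"),
            fontsize=8,
            frameon=False,
        )
    if path is not None:
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        return None
    return fig


def _draw_panel(panel: Panel, ax):
    for s in panel.shades:
        ax.axvspan(s.x0, s.x1, color=s.fill, alpha=s.alpha, zorder=0, linewidth=0)
    for r in panel.rects:
        ax.axvspan(r.x0, r.x1, color=r.color, alpha=r.alpha, zorder=3, linewidth=0)
    mirrored = False
    for series in panel.points:
        filled = getattr(series, "filled", True)
        ax.scatter(
            series.x,
            series.y,
            s=series.size**2,
            c=series.color if filled else "none",
            edgecolors=series.color,
            marker=series.marker,
            alpha=series.alpha,
            linewidths=0.8,
            zorder=2,
            label=series.dataset,
        )
        mirrored = mirrored or series.orientation == "bottom"
    for h in panel.hlines:
        ax.axhline(h.y, color=h.color, linestyle=h.linestyle, linewidth=0.8, zorder=1)
    for v in panel.vlines:
        ax.axvline(v.x, color=v.color, linestyle=v.linestyle, linewidth=0.8, zorder=1)
    for a in panel.alines:
        ax.axline((0, a.intercept), slope=a.slope, color=a.color,
                  linestyle=a.linestyle, linewidth=0.8, zorder=1)
    for lab in panel.labels:
        ax.annotate(
            lab.text,
            (lab.x, lab.y),
            xytext=(lab.x + lab.nudge_x, lab.y + lab.nudge_y + 0.4),
            fontsize=7,
            color=lab.color,
            rotation=lab.angle,
            ha="center",
            zorder=4,
            **_FONTFACE.get(lab.fontface, _FONTFACE["plain"]),
        )
    if panel.kind == "genes":
        _draw_genes(panel, ax)
    if panel.x_range:
        ax.set_xlim(panel.x_range)
    if panel.xaxis:
        if panel.xaxis.ticks:
            ax.set_xticks(panel.xaxis.ticks)
            ax.set_xticklabels(panel.xaxis.tick_labels, fontsize=7)
        if panel.xaxis.label:
            ax.set_xlabel(panel.xaxis.label)
    if panel.y_label:
        ax.set_ylabel(panel.y_label)
    if mirrored:
        # mirrored series carry negative y; show magnitudes on the axis
        ax.yaxis.set_major_formatter(FuncFormatter(lambda v, _: f"{abs(v):g}"))
    if panel.kind in ("main", "overview") and not mirrored:
        ax.set_ylim(bottom=0)


def _draw_genes(panel: Panel, ax):
    n_rows = max((g.row for g in panel.genes), default=0) + 1
    for g in panel.genes:
        y = n_rows - 1 - g.row
        ax.hlines(y, g.start, g.end, color="#2255aa", linewidth=2 if not g.exons else 1)
        for s, e in g.exons:
            ax.add_patch(
                Rectangle((s, y - 0.18), max(e - s, 1), 0.36, color="#2255aa", linewidth=0)
            )
        ax.text(g.start, y + 0.28, g.name, fontsize=7, fontstyle="italic", va="bottom")
    ax.set_ylim(-0.6, n_rows + 0.2)
    ax.set_yticks([])
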