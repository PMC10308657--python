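"""Declarative, renderer-independent figure descriptions and layout maths.

Every plot function computes a :class:`PlotSpec` — panels of point series,
chromosome shades, threshold lines, labels and gene glyphs in data
coordinates — and the renderer consumes nothing else.  This keeps layout
logic deterministic and testable (specs serialise to JSON for golden
comparisons) without any image diffing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ValidationError
from .sumstats import CHROM_RANK, GwasDataset

#: Fixed qualitative palette indexed by dataset order.
PALETTE = (
    "#2c6b9e",
    "#e8702a",
    "#1fa187",
    "#b2403d",
    "#7b5fa2",
    "#5d8a31",
    "#a66f23",
    "#d16ba5",
)

#: Inter-chromosome gap as a fraction of the total genome span.
CHROM_GAP_FRAC = 0.003


@dataclass
class PointSeries:
    dataset: str
    x: list = field(default_factory=list)
    y: list = field(default_factory=list)
    color: str = PALETTE[0]
    marker: str = "o"
    size: float = 4.0
    alpha: float = 0.8
    orientation: str = "top"  # top: y = -log10 p; bottom: y = log10 p
    filled: bool = True


@dataclass
class Shade:
    x0: float
    x1: float
    fill: str = "#cccccc"
    alpha: float = 0.3


@dataclass
class HLine:
    y: float
    color: str = "#888888"
    linestyle: str = "dashed"


@dataclass
class VLine:
    x: float
    color: str = "#555555"
    linestyle: str = "dashed"


@dataclass
class ALine:
    """A reference line y = slope * x + intercept (identity line etc.)."""

    slope: float = 1.0
    intercept: float = 0.0
    color: str = "#aaaaaa"
    linestyle: str = "dotted"


@dataclass
class Label:
    x: float
    y: float
    text: str
    color: str = "black"
    fontface: str = "plain"  # plain | bold | italic
    angle: float = 0.0
    nudge_x: float = 0.0
    nudge_y: float = 0.0


@dataclass
class Rect:
    x0: float
    x1: float
    color: str = "red"
    alpha: float = 0.9


@dataclass
class GeneGlyph:
    name: str
    start: float
    end: float
    row: int
    exons: list = field(default_factory=list)
    show_exons: bool = False


@dataclass
class Axis:
    ticks: list = field(default_factory=list)
    tick_labels: list = field(default_factory=list)
    label: str = ""


@dataclass
class Panel:
    kind: str  # overview | main | genes
    points: list = field(default_factory=list)
    shades: list = field(default_factory=list)
    hlines: list = field(default_factory=list)
    vlines: list = field(default_factory=list)
    alines: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    rects: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    x_range: tuple | None = None
    xaxis: Axis | None = None
    y_label: str = ""
    height: float = 1.0  # relative panel height


@dataclass
class Legend:
    entries: list = field(default_factory=list)  # (label, color) pairs
    position: str = "top right"


@dataclass
class PlotSpec:
    panels: list = field(default_factory=list)
    legend: Legend | None = None
    title: str = ""
    region_text: str | None = None

    def panel(self, kind: str) -> Panel:
        for p in self.panels:
            if p.kind == kind:
                return p
        raise KeyError(f"no {kind!r} panel in this spec")

    def to_dict(self) -> dict:
        return _plain(asdict(self))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _plain(obj):
    """Recursively convert numpy scalars/arrays to JSON-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    return obj


# -- genome layout ---------------------------------------------------------


@dataclass
class GenomeLayout:
    """Cumulative x-coordinate map over the chromosomes on display."""

    offsets: dict  # chrom -> cumulative offset
    spans: dict  # chrom -> span (max position observed)
    gap: float

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.offsets, key=CHROM_RANK.__getitem__)

    @property
    def total(self) -> float:
        last = self.chromosomes[-1]
        return self.offsets[last] + self.spans[last]

    def x(self, chrom, pos):
        """Cumulative x for positions on one chromosome (vectorised)."""
        return self.offsets[chrom] + np.asarray(pos)

    def shades(self, fill: str = "#cccccc", alpha: float = 0.3) -> list[Shade]:
        """Alternating background rectangles, one per odd-indexed chromosome."""
        out = []
        for i, c in enumerate(self.chromosomes):
            if i % 2 == 1:
                out.append(Shade(self.offsets[c], self.offsets[c] + self.spans[c], fill, alpha))
        return out

    def ticks(self) -> Axis:
        chroms = self.chromosomes
        return Axis(
            ticks=[self.offsets[c] + self.spans[c] / 2 for c in chroms],
            tick_labels=chroms,
            label="Chromosome",
        )


def genome_layout(
    datasets: list[GwasDataset], gap_frac: float = CHROM_GAP_FRAC
) -> GenomeLayout:
    """Cumulative coordinates over all chromosomes present in any dataset.

    A chromosome's span is the largest position observed for it; each
    chromosome is offset by the summed spans of its predecessors plus a
    fixed gap (``gap_frac`` of the total genome span).
    """
    if not datasets or all(len(d) == 0 for d in datasets):
        raise ValidationError("genome layout needs at least one variant")
    spans: dict[str, int] = {}
    for d in datasets:
        for chrom, mx in d.df.groupby("CHROM")["POS"].max().items():
            spans[chrom] = max(spans.get(chrom, 0), int(mx))
    chroms = sorted(spans, key=CHROM_RANK.__getitem__)
    gap = gap_frac * sum(spans.values())
    offsets, cum = {}, 0.0
    for i, c in enumerate(chroms):
        offsets[c] = cum
        cum += spans[c] + gap
    return GenomeLayout(offsets=offsets, spans=spans, gap=gap)


def split_ntop(n_datasets: int, ntop: int | None) -> list[str]:
    """Orientation per dataset: the first ``ntop`` go on top, the rest are
    mirrored below; ``ntop=None`` puts everything on a single upward axis."""
    if ntop is None:
        ntop = n_datasets
    if not (0 <= ntop <= n_datasets):
        raise ValidationError(
            f"ntop must lie in [0, {n_datasets}], got {ntop}"
        )
    return ["top"] * ntop + ["bottom"] * (n_datasets - ntop)


def broadcast_option(value, n: int, default, what: str = "option") -> list:
    """Expand a scalar or per-dataset vector option to length ``n``."""
    if value is None:
        value = default
    if isinstance(value, (list, tuple)):
        if len(value) == 1:
            return list(value) * n
        if len(value) != n:
            raise ValidationError(
                f"{what} vector has length {len(value)}, expected 1 or {n}"
            )
        return list(value)
    return [value] * n


def mlog10(p) -> np.ndarray:
    return -np.log10(np.asarray(p, dtype=float))


def repel_labels(labels: list[Label], x_range: float, step: float = 0.6) -> list[Label]:
    """Greedy vertical repel of labels closer than 1% of the x-range.

    User-supplied nudges are applied afterwards by the caller and therefore
    always take precedence over the automatic offsets.
    """
    min_dx = 0.01 * x_range
    out = sorted(labels, key=lambda l: (l.x, l.text))
    bump = 0.0
    for prev, cur in zip(out, out[1:]):
        if abs(cur.x - prev.x) < min_dx:
            bump += step
            cur.nudge_y += bump
        else:
            bump = 0.0
    return out
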