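"""Manhattan, regional, locuszoom-style and effect-comparison plot builders.

Each function assembles a :class:`~gwasviz.plotspec.PlotSpec`; pass it to
:func:`gwasviz.render.render` (or use ``out=`` on the CLI) to draw it with
matplotlib.  All functions accept one dataset or an ordered list; style
options (color, marker, size, alpha, annotate, ...) may be scalars or
per-dataset vectors aligned with that order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingColumnError, ValidationError
from .genes import GeneModel, GeneTrack, annotate_with_nearest_gene
from .plotspec import (
    ALine,
    Axis,
    GeneGlyph,
    HLine,
    Label,
    Legend,
    Panel,
    PlotSpec,
    PointSeries,
    Rect,
    Shade,
    VLine,
    PALETTE,
    broadcast_option,
    genome_layout,
    mlog10,
    repel_labels,
    split_ntop,
)
from .regions import (
    DEFAULT_GENE_PADDING,
    DEFAULT_REGION_SIZE,
    DEFAULT_THRESH,
    DEFAULT_VARIANT_FLANK,
    Region,
    get_lead_snps,
    get_snps_within_region,
    resolve_region,
)
from .snpset import GENOME_WIDE_P, SnpSetReport, effect_table
from .sumstats import GwasDataset

#: Width below which regional gene panels show exon structure.
EXON_DETAIL_MAX_WIDTH = 1_000_000

#: Minimum drawn width of the overview rectangle, as a fraction of the
#: chromosome span, so that tiny regions stay visible ("may appear as a line").
MIN_OVERVIEW_RECT_FRAC = 0.005

#: Panel height proportions for regional plots (overview : main : genes).
REGION_PANEL_HEIGHTS = (1.0, 4.0, 1.0)

#: r^2 bin edges and the conventional locuszoom-style colours per bin.
R2_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
R2_COLORS = ("#2c2c86", "#77b4e4", "#4daf4a", "#ff7f00", "#e41a1c")


def _as_list(datasets) -> list[GwasDataset]:
    ds = [datasets] if isinstance(datasets, GwasDataset) else list(datasets)
    if not ds:
        raise ValidationError("at least one dataset is required")
    labels = [d.label for d in ds]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"dataset labels must be unique, got {labels}")
    return ds


def select_labels(
    datasets,
    annotate,
    region_size: int = DEFAULT_REGION_SIZE,
    annotate_with: str = "gene",
    track: GeneTrack | None = None,
) -> list[pd.DataFrame]:
    """Per-dataset lead variants to label, with their display text.

    ``annotate`` is a p-value threshold, a per-dataset vector of thresholds
    (length 1 or n), or None for no labels.  Text comes from an existing
    GENE column when present, else the nearest gene (``annotate_with =
    'gene'``, requires a track) or the variant ID (``'id'``).
    """
    ds = _as_list(datasets)
    if annotate is None:
        return [d.df.iloc[0:0].assign(text=pd.Series(dtype=str)) for d in ds]
    threshes = broadcast_option(annotate, len(ds), None, "annotate")
    out = []
    for d, th in zip(ds, threshes):
        leads = get_lead_snps(d, thresh=th, region_size=region_size)
        if "GENE" in leads.columns and leads["GENE"].notna().all() and len(leads):
            leads["text"] = leads["GENE"]
        elif annotate_with == "gene" and track is not None:
            leads = annotate_with_nearest_gene(leads, track, column="text")
        elif "ID" in leads.columns:
            leads["text"] = leads["ID"]
        else:
            leads["text"] = [
                f"{c}:{p}" for c, p in zip(leads["CHROM"], leads["POS"])
            ]
        out.append(leads)
    return out


def _styles(ds, color, marker, size, alpha):
    n = len(ds)
    return (
        broadcast_option(color, n, [PALETTE[i % len(PALETTE)] for i in range(n)], "color"),
        broadcast_option(marker, n, "o", "shape"),
        broadcast_option(size, n, 4.0, "size"),
        broadcast_option(alpha, n, 0.8, "alpha"),
    )


def _sign_lines(sign_thresh, orientations) -> list[HLine]:
    if sign_thresh is None:
        return []
    vals = sign_thresh if isinstance(sign_thresh, (list, tuple)) else [sign_thresh]
    lines = []
    for v in vals:
        lines.append(HLine(y=float(mlog10(v)), color="#cc0000"))
        if "bottom" in orientations:
            lines.append(HLine(y=-float(mlog10(v)), color="#cc0000"))
    return lines


def _point_series(ds, xs, orientations, colors, markers, sizes, alphas):
    series = []
    for d, x, orient, c, m, s, a in zip(ds, xs, orientations, colors, markers, sizes, alphas):
        y = mlog10(d.df["P"])
        if orient == "bottom":
            y = -y
        series.append(
            PointSeries(
                dataset=d.label,
                x=list(np.asarray(x, dtype=float)),
                y=list(y),
                color=c,
                marker=m,
                size=s,
                alpha=a,
                orientation=orient,
            )
        )
    return series


def _find_rsids(ds: list[GwasDataset], rsids: Sequence[str]) -> list[tuple[int, pd.Series]]:
    hits = []
    for i, d in enumerate(ds):
        if "ID" not in d.df.columns:
            continue
        sub = d.df[d.df["ID"].isin(list(rsids))]
        for _, row in sub.iterrows():
            hits.append((i, row))
    return hits


def manhattan(
    datasets,
    annotate=None,
    annotate_with_vline: bool = False,
    region_size: int = DEFAULT_REGION_SIZE,
    ntop: int | None = None,
    sign_thresh=GENOME_WIDE_P,
    highlight_genes: Sequence[str] | None = None,
    vline=None,
    rsids: Sequence[str] | None = None,
    rsids_with_vline: Sequence[str] | None = None,
    color=None,
    shape=None,
    size=None,
    alpha=None,
    shade_color: str = "#cccccc",
    shade_alpha: float = 0.3,
    legend: bool = True,
    legend_position: str = "top right",
    track: GeneTrack | None = None,
    annotate_with: str = "gene",
    nudge_x=0.0,
    nudge_y=0.0,
    angle=0.0,
    fontface="plain",
    title: str = "",
) -> PlotSpec:
    """A genome-wide Manhattan spec for one or several datasets.

    Points sit at cumulative genomic x versus -log10(p); alternating
    semi-transparent shades distinguish the chromosomes; a genome-wide
    significance line at p = 5e-8 is drawn by default (set ``sign_thresh``
    to None to remove it, or to a list for multiple thresholds).  With
    ``ntop`` fewer than the number of datasets the remainder are mirrored
    below a reversed y-axis.  ``annotate`` switches on lead labelling;
    ``highlight_genes`` adds named gene markers on a bottom strip.
    """
    ds = _as_list(datasets)
    layout = genome_layout(ds)
    orientations = split_ntop(len(ds), ntop)
    colors, markers, sizes, alphas = _styles(ds, color, shape, size, alpha)
    xs = [
        d.df["CHROM"].map(layout.offsets).to_numpy(dtype=float)
        + d.df["POS"].to_numpy(dtype=float)
        for d in ds
    ]

    panel = Panel(
        kind="main",
        points=_point_series(ds, xs, orientations, colors, markers, sizes, alphas),
        shades=layout.shades(fill=shade_color, alpha=shade_alpha),
        hlines=_sign_lines(sign_thresh, orientations),
        xaxis=layout.ticks(),
        x_range=(0.0, float(layout.total)),
        y_label="-log10(P)",
        height=4.0,
    )

    nudge_xs = broadcast_option(nudge_x, len(ds), 0.0, "nudge_x")
    nudge_ys = broadcast_option(nudge_y, len(ds), 0.0, "nudge_y")
    angles = broadcast_option(angle, len(ds), 0.0, "angle")
    faces = broadcast_option(fontface, len(ds), "plain", "fontface")

    label_sets = select_labels(ds, annotate, region_size, annotate_with, track)
    for i, (d, leads, orient) in enumerate(zip(ds, label_sets, orientations)):
        labs = []
        for _, row in leads.iterrows():
            lx = float(layout.x(row["CHROM"], row["POS"]))
            ly = float(mlog10(row["P"]))
            if orient == "bottom":
                ly = -ly
            labs.append(
                Label(
                    x=lx, y=ly, text=str(row["text"]),
                    color=colors[i], fontface=faces[i], angle=angles[i],
                    nudge_x=nudge_xs[i], nudge_y=nudge_ys[i],
                )
            )
            if annotate_with_vline:
                panel.vlines.append(VLine(x=lx))
        panel.labels.extend(repel_labels(labs, layout.total))

    if vline is not None:
        for v in vline if isinstance(vline, (list, tuple)) else [vline]:
            chrom, pos = (v if isinstance(v, tuple) else _parse_vline(v))
            panel.vlines.append(VLine(x=float(layout.x(chrom, pos))))
    for arg, with_line in ((rsids, False), (rsids_with_vline, True)):
        if arg:
            for i, row in _find_rsids(ds, arg):
                lx = float(layout.x(row["CHROM"], row["POS"]))
                ly = float(mlog10(row["P"]))
                if orientations[i] == "bottom":
                    ly = -ly
                panel.labels.append(
                    Label(x=lx, y=ly, text=str(row["ID"]), color=colors[i],
                          nudge_x=nudge_xs[i], nudge_y=nudge_ys[i], angle=angles[i])
                )
                if with_line:
                    panel.vlines.append(VLine(x=lx))

    panels = [panel]
    if highlight_genes:
        if track is None:
            raise ValidationError("highlight_genes requires a gene track")
        glyphs = []
        for name in highlight_genes:
            g = track.by_name(name)
            glyphs.append(
                GeneGlyph(
                    name=g.gene_name,
                    start=float(layout.x(g.chrom, g.gene_start)),
                    end=float(layout.x(g.chrom, g.gene_end)),
                    row=0,
                )
            )
        panels.append(
            Panel(kind="genes", genes=glyphs, x_range=panel.x_range, height=0.6)
        )

    spec = PlotSpec(panels=panels, title=title)
    if len(ds) > 1 and legend:
        spec.legend = Legend(
            entries=[(d.label, c) for d, c in zip(ds, colors)],
            position=legend_position,
        )
    return spec


def _parse_vline(v):
    from .sumstats import canonical_chrom

    if isinstance(v, str) and ":" in v:
        chrom, _, pos = v.partition(":")
        return canonical_chrom(chrom), int(pos.replace(",", ""))
    raise ValidationError(f"vline must be (chrom, pos) or 'chrom:pos', got {v!r}")


# -- gene-row packing ------------------------------------------------------


def pack_gene_rows(
    genes: Sequence[GeneModel],
    region: Region,
    show_exons: bool,
    char_width_frac: float = 0.012,
) -> list[GeneGlyph]:
    """Pack gene glyphs into rows with no horizontal overlap.

    Each glyph's extent covers the gene span plus its name label, whose
    width is estimated at ``char_width_frac`` of the region width per
    character.  Genes are placed left-to-right into the first row whose
    previous glyph ends before this one starts.
    """
    width = max(region.width, 1)
    row_ends: list[float] = []
    glyphs: list[GeneGlyph] = []
    pad = 0.005 * width
    for g in sorted(genes, key=lambda g: (g.gene_start, g.gene_name)):
        label_w = (len(g.gene_name) + 1) * char_width_frac * width
        start = float(g.gene_start)
        extent_end = max(float(g.gene_end), start + label_w)
        row = next(
            (i for i, e in enumerate(row_ends) if start > e + pad), len(row_ends)
        )
        if row == len(row_ends):
            row_ends.append(extent_end)
        else:
            row_ends[row] = extent_end
        glyphs.append(
            GeneGlyph(
                name=g.gene_name,
                start=start,
                end=float(g.gene_end),
                row=row,
                exons=[list(e) for e in g.exons] if show_exons else [],
                show_exons=show_exons,
            )
        )
    return glyphs


def _gene_panel(track, region, show_exons, height=1.0):
    genes = track.genes_in_region(region.chrom, region.start, region.end) if track else []
    return Panel(
        kind="genes",
        genes=pack_gene_rows(genes, region, show_exons),
        x_range=(float(region.start), float(region.end)),
        height=height,
    )


def regionplot(
    datasets,
    gene: str | None = None,
    variant: str | None = None,
    region=None,
    track: GeneTrack | None = None,
    gene_padding: int = DEFAULT_GENE_PADDING,
    variant_flank: int = DEFAULT_VARIANT_FLANK,
    annotate=None,
    region_size: int = DEFAULT_REGION_SIZE,
    sign_thresh=GENOME_WIDE_P,
    show_exons: bool | None = None,
    annotate_with: str = "id",
    vline=None,
    rsids: Sequence[str] | None = None,
    color=None,
    shape=None,
    size=None,
    alpha=None,
    legend: bool = True,
    legend_position: str = "top right",
    title: str = "",
) -> PlotSpec:
    """A three-panel regional spec: chromosome overview, main and genes.

    The region comes from a gene name (span + ``gene_padding`` each side),
    a variant ID (position +/- ``variant_flank``) or literal coordinates.
    The overview shows the whole chromosome with a red rectangle over the
    displayed region; the gene panel shows exon structure for regions
    narrower than 1 Mb (override with ``show_exons``).  The resolved
    coordinates are embedded in the spec and shown on the figure.
    """
    ds = _as_list(datasets)
    reg = resolve_region(
        gene=gene, variant=variant, region=region,
        data=ds[0], track=track,
        gene_padding=gene_padding, variant_flank=variant_flank,
    )
    orientations = split_ntop(len(ds), None)
    colors, markers, sizes, alphas = _styles(ds, color, shape, size, alpha)

    chrom_span = max(
        [int(d.df.loc[d.df["CHROM"] == reg.chrom, "POS"].max()) for d in ds if (d.df["CHROM"] == reg.chrom).any()]
        + [reg.end]
    )
    over_sets = [d.subset(d.df["CHROM"] == reg.chrom) for d in ds]
    overview = Panel(
        kind="overview",
        points=_point_series(
            over_sets,
            [d.df["POS"].to_numpy(dtype=float) for d in over_sets],
            orientations, colors, markers,
            [max(1.0, s * 0.5) for s in sizes], alphas,
        ),
        rects=[_overview_rect(reg, chrom_span)],
        x_range=(1.0, float(chrom_span)),
        y_label="-log10(P)",
        height=REGION_PANEL_HEIGHTS[0],
    )

    region_sets = [d.subset(get_snps_within_region(d, reg)) for d in ds]
    main = Panel(
        kind="main",
        points=_point_series(
            region_sets,
            [d.df["POS"].to_numpy(dtype=float) for d in region_sets],
            orientations, colors, markers, sizes, alphas,
        ),
        hlines=_sign_lines(sign_thresh, orientations),
        x_range=(float(reg.start), float(reg.end)),
        xaxis=Axis(label=f"Position on chromosome {reg.chrom}"),
        y_label="-log10(P)",
        height=REGION_PANEL_HEIGHTS[1],
    )
    label_sets = select_labels(region_sets, annotate, region_size, annotate_with, track)
    for i, leads in enumerate(label_sets):
        labs = [
            Label(
                x=float(r["POS"]), y=float(mlog10(r["P"])), text=str(r["text"]),
                color=colors[i],
            )
            for _, r in leads.iterrows()
        ]
        main.labels.extend(repel_labels(labs, reg.width))
        main.vlines.extend(VLine(x=l.x) for l in labs)
    if rsids:
        for i, row in _find_rsids(region_sets, rsids):
            main.labels.append(
                Label(x=float(row["POS"]), y=float(mlog10(row["P"])),
                      text=str(row["ID"]), color=colors[i])
            )
    if vline is not None:
        for v in vline if isinstance(vline, (list, tuple)) else [vline]:
            pos = v[1] if isinstance(v, tuple) else _parse_vline(v)[1]
            main.vlines.append(VLine(x=float(pos)))

    exons = reg.width < EXON_DETAIL_MAX_WIDTH if show_exons is None else show_exons
    panels = [overview, main, _gene_panel(track, reg, exons, REGION_PANEL_HEIGHTS[2])]
    spec = PlotSpec(panels=panels, title=title, region_text=str(reg))
    if len(ds) > 1 and legend:
        spec.legend = Legend(
            entries=[(d.label, c) for d, c in zip(ds, colors)],
            position=legend_position,
        )
    return spec


def _overview_rect(region: Region, chrom_span: int) -> Rect:
    min_w = MIN_OVERVIEW_RECT_FRAC * chrom_span
    x0, x1 = float(region.start), float(region.end)
    if x1 - x0 < min_w:
        mid = (x0 + x1) / 2
        x0, x1 = mid - min_w / 2, mid + min_w / 2
    return Rect(x0=x0, x1=x1)


def r2_bin(values) -> np.ndarray:
    """Bin r^2 values into the five conventional intervals (index 0..4)."""
    v = np.asarray(values, dtype=float)
    idx = np.digitize(v, R2_BINS[1:-1], right=False)
    return np.clip(idx, 0, len(R2_COLORS) - 1)


def locuszoom(
    data: GwasDataset,
    gene: str | None = None,
    variant: str | None = None,
    region=None,
    track: GeneTrack | None = None,
    gene_padding: int = DEFAULT_GENE_PADDING,
    variant_flank: int = DEFAULT_VARIANT_FLANK,
    annotate=None,
    region_size: int = DEFAULT_REGION_SIZE,
    sign_thresh=GENOME_WIDE_P,
    show_exons: bool | None = None,
    title: str = "",
) -> PlotSpec:
    """A regional spec coloured by pre-computed r^2 against an index variant.

    The dataset must carry an R2 column (pairwise correlation of each
    variant with the index variant, computed beforehand with external LD
    software).  Points are coloured by r^2 bin; a variant with r^2 = 1, if
    present, is drawn distinctly as the index variant.
    """
    if "R2" not in data.df.columns:
        raise MissingColumnError(["r2 (pre-calculate r^2 against the index variant)"])
    if region is None and gene is None and variant is None:
        df = data.df
        reg = Region(
            df["CHROM"].iloc[0],
            int(df.loc[df["CHROM"] == df["CHROM"].iloc[0], "POS"].min()),
            int(df.loc[df["CHROM"] == df["CHROM"].iloc[0], "POS"].max()),
            provenance="literal",
        )
    else:
        reg = resolve_region(
            gene=gene, variant=variant, region=region, data=data, track=track,
            gene_padding=gene_padding, variant_flank=variant_flank,
        )
    sub = get_snps_within_region(data, reg)
    bins = r2_bin(sub["R2"])
    is_index = sub["R2"].to_numpy() >= 1.0

    main = Panel(
        kind="main",
        hlines=_sign_lines(sign_thresh, ["top"]),
        x_range=(float(reg.start), float(reg.end)),
        xaxis=Axis(label=f"Position on chromosome {reg.chrom}"),
        y_label="-log10(P)",
        height=REGION_PANEL_HEIGHTS[1],
    )
    entries = []
    for b in range(len(R2_COLORS)):
        mask = (bins == b) & ~is_index
        if not mask.any():
            continue
        lab = f"{R2_BINS[b]:.1f}-{R2_BINS[b + 1]:.1f}"
        main.points.append(
            PointSeries(
                dataset=lab,
                x=list(sub.loc[mask, "POS"].astype(float)),
                y=list(mlog10(sub.loc[mask, "P"])),
                color=R2_COLORS[b],
            )
        )
        entries.append((lab, R2_COLORS[b]))
    if is_index.any():
        main.points.append(
            PointSeries(
                dataset="index variant",
                x=list(sub.loc[is_index, "POS"].astype(float)),
                y=list(mlog10(sub.loc[is_index, "P"])),
                color="#9632b8",
                marker="D",
                size=7.0,
            )
        )
        entries.append(("index variant", "#9632b8"))
    if annotate is not None:
        labels = select_labels(
            [GwasDataset(df=sub, label=data.label)], annotate, region_size, "id", track
        )[0]
        main.labels.extend(
            Label(x=float(r["POS"]), y=float(mlog10(r["P"])), text=str(r["text"]))
            for _, r in labels.iterrows()
        )

    exons = reg.width < EXON_DETAIL_MAX_WIDTH if show_exons is None else show_exons
    spec = PlotSpec(
        panels=[main, _gene_panel(track, reg, exons, REGION_PANEL_HEIGHTS[2])],
        title=title,
        region_text=str(reg),
        legend=Legend(entries=entries, position="top right"),
    )
    return spec


def effectplot(
    d1: GwasDataset | None = None,
    d2: GwasDataset | None = None,
    snpset=None,
    track: GeneTrack | None = None,
    thresh: float = DEFAULT_THRESH,
    region_size: int = DEFAULT_REGION_SIZE,
    sign_thresh2: float = GENOME_WIDE_P,
    color: str = PALETTE[0],
    title: str = "",
    xlabel: str | None = None,
    ylabel: str | None = None,
) -> PlotSpec:
    """Effect sizes of dataset-1 lead variants against dataset 2.

    Accepts two datasets (a snpset is built internally, accepting a
    :class:`SnpSetReport` as well) or a ready snpset table.  Each variant
    is a filled circle with a black gene label when its dataset-2 p-value
    is below 5e-8, otherwise an unfilled circle with a grey label.  The
    identity line and zero axes are drawn for orientation.
    """
    if isinstance(snpset, SnpSetReport):
        snpset = snpset.snpset
    table = effect_table(
        d1=d1, d2=d2, snpset=snpset, track=track,
        thresh=thresh, region_size=region_size, sign_thresh2=sign_thresh2,
    )
    panel = Panel(
        kind="effect",
        hlines=[HLine(y=0.0, color="#999999", linestyle="solid")],
        vlines=[VLine(x=0.0, color="#999999", linestyle="solid")],
        alines=[ALine(slope=1.0, intercept=0.0)],
        xaxis=Axis(label=xlabel or (f"Effect ({d1.label})" if d1 is not None else "Effect (D1)")),
        y_label=ylabel or (f"Effect ({d2.label})" if d2 is not None else "Effect (D2)"),
        height=4.0,
    )
    for flag, filled in ((True, True), (False, False)):
        rows = table[table["significant2"] == flag]
        if len(rows) == 0 and flag is False:
            continue
        panel.points.append(
            PointSeries(
                dataset="P2 < %.0e" % sign_thresh2 if flag else "P2 >= %.0e" % sign_thresh2,
                x=list(rows["E1"].astype(float)),
                y=list(rows["E2"].astype(float)),
                color=color,
                filled=filled,
            )
        )
        panel.labels.extend(
            Label(
                x=float(r["E1"]), y=float(r["E2"]), text=str(r["gene"]),
                color="black" if flag else "#888888",
            )
            for _, r in rows.iterrows()
        )
    return PlotSpec(panels=[panel], title=title)
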