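"""Lead-variant selection, region resolution and regional extraction.

A *lead* (index) variant is the most significant variant within a genomic
window; one lead is reported per association peak.  Selection is greedy:
repeatedly take the remaining variant with the smallest p-value below the
threshold, then exclude every variant within ``region_size / 2`` bp on each
side, i.e. a window of total width ``region_size`` centred on the lead.
The exclusion boundary is strict: a variant exactly ``region_size / 2``
away is kept as a potential lead.  P-value ties are broken by the smaller
position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RegionParseError, ValidationError, VariantNotFoundError
from .sumstats import CHROM_RANK, GwasDataset, canonical_chrom

DEFAULT_THRESH = 5e-8
DEFAULT_REGION_SIZE = 1_000_000
DEFAULT_GENE_PADDING = 100_000
DEFAULT_VARIANT_FLANK = 100_000


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive chromosome interval with provenance."""

    chrom: str
    start: int
    end: int
    provenance: str = "literal"  # gene | variant | literal
    label: str | None = None

    def __post_init__(self):
        if self.start < 1:
            raise ValidationError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_REGION_RE = re.compile(
    r"^(?:chr)?(?P<chrom>[0-9XYMTxymt]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$"
)


def parse_region_string(text: str) -> Region:
    """Parse ``"chrom:start-end"``; 'chr' prefixes and thousands separators ok."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise RegionParseError(
            f"cannot parse region {text!r}; expected 'chrom:start-end'"
        )
    chrom = canonical_chrom(m.group("chrom"))
    if chrom is None:
        raise RegionParseError(f"non-canonical chromosome in region {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return Region(chrom, start, end, provenance="literal")


def get_lead_snps(
    data: GwasDataset | pd.DataFrame,
    thresh: float = DEFAULT_THRESH,
    region_size: int = DEFAULT_REGION_SIZE,
) -> pd.DataFrame:
    """Greedy per-window lead-variant selection.

    Returns the selected rows (all original columns plus a per-chromosome
    ``lead_rank`` giving selection order) sorted by chromosome rank then
    position.  Variants with ``P >= thresh`` are never leads.
    """
    if region_size <= 0:
        raise ValidationError(f"region_size must be positive, got {region_size}")
    if not (0 < thresh <= 1):
        raise ValidationError(f"thresh must lie in (0, 1], got {thresh}")
    df = data.df if isinstance(data, GwasDataset) else data
    sig = df[df["P"] < thresh]
    half = region_size / 2
    picked: list[pd.DataFrame] = []
    for chrom, grp in sig.groupby("CHROM", sort=False):
        order = grp.sort_values(["P", "POS"], kind="stable")
        accepted_pos: list[int] = []
        accepted_idx: list = []
        for idx, pos in zip(order.index, order["POS"]):
            if all(abs(pos - a) >= half for a in accepted_pos):
                accepted_pos.append(pos)
                accepted_idx.append(idx)
        sel = grp.loc[accepted_idx].copy()
        sel["lead_rank"] = range(1, len(sel) + 1)
        picked.append(sel)
    if not picked:
        out = df.iloc[0:0].copy()
        out["lead_rank"] = pd.Series(dtype=int)
        return out
    out = pd.concat(picked)
    rank = out["CHROM"].map(CHROM_RANK)
    return (
        out.assign(_rank=rank)
        .sort_values(["_rank", "POS"], kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )


def resolve_region(
    gene: str | None = None,
    variant: str | None = None,
    region: str | tuple | Region | None = None,
    data: GwasDataset | None = None,
    track=None,
    gene_padding: int = DEFAULT_GENE_PADDING,
    variant_flank: int = DEFAULT_VARIANT_FLANK,
) -> Region:
    """Resolve exactly one of gene / variant / region into a Region.

    * gene: the gene span padded by ``gene_padding`` on each side (clipped
      at position 1); requires ``track``.
    * variant: the variant's position +/- ``variant_flank``; requires
      ``data`` carrying an ID column.
    * region: a ``"chrom:start-end"`` string, ``(chrom, start, end)`` tuple
      or an existing Region, passed through verbatim.
    """
    supplied = [x is not None for x in (gene, variant, region)]
    if sum(supplied) != 1:
        raise ValidationError("supply exactly one of gene=, variant= or region=")

    if gene is not None:
        if track is None:
            raise ValidationError("a gene track is required to resolve a gene region")
        g = track.by_name(gene)
        return Region(
            g.chrom,
            max(1, g.gene_start - gene_padding),
            g.gene_end + gene_padding,
            provenance="gene",
            label=g.gene_name,
        )

    if variant is not None:
        if data is None or "ID" not in data.df.columns:
            raise VariantNotFoundError(
                f"variant {variant!r}: dataset with an ID column is required"
            )
        hit = data.df[data.df["ID"] == variant]
        if hit.empty:
            raise VariantNotFoundError(f"variant {variant!r} not found in {data.label}")
        row = hit.iloc[0]
        pos = int(row["POS"])
        return Region(
            row["CHROM"],
            max(1, pos - variant_flank),
            pos + variant_flank,
            provenance="variant",
            label=variant,
        )

    if isinstance(region, Region):
        return region
    if isinstance(region, str):
        return parse_region_string(region)
    chrom, start, end = region
    c = canonical_chrom(chrom)
    if c is None:
        raise RegionParseError(f"non-canonical chromosome {chrom!r}")
    return Region(c, int(start), int(end), provenance="literal")


def get_snps_within_region(
    data: GwasDataset | pd.DataFrame, region: Region
) -> pd.DataFrame:
    """Rows with CHROM = region.chrom and start <= POS <= end, order kept."""
    df = data.df if isinstance(data, GwasDataset) else data
    mask = (
        (df["CHROM"] == region.chrom)
        & (df["POS"] >= region.start)
        & (df["POS"] <= region.end)
    )
    return df[mask].copy()
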