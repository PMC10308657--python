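"""Gene/exon models and overlap / nearest-gene / coordinate queries.

A :class:`GeneTrack` holds gene models (span + merged exon intervals) for
one genome build, indexed per chromosome with an interval tree for overlap
queries and sorted boundary arrays for nearest-gene queries.  Coordinates
are 1-based inclusive, matching Ensembl gene annotation.

Tie rules (deterministic by design):

* position inside two or more overlapping genes -> the gene with the
  smaller span wins (most specific), then alphabetical;
* exact equidistance between two genes -> alphabetically first symbol.

Distance is unstranded base pairs to the nearer gene boundary, not to the
transcription start site.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import GeneNotFoundError, MissingColumnError, ValidationError
from .sumstats import CHROM_RANK, canonical_chrom

logger = logging.getLogger(__name__)

#: Sentinel gene symbol used when a position has no candidate gene.
NO_GENE = "no gene"


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


@dataclass(frozen=True)
class GeneModel:
    """One gene: symbol, span, biotype and merged exon intervals."""

    gene_name: str
    chrom: str
    gene_start: int
    gene_end: int
    biotype: str = "protein_coding"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.gene_start > self.gene_end:
            raise ValidationError(
                f"{self.gene_name}: gene_start {self.gene_start} > gene_end {self.gene_end}"
            )
        merged = tuple(merge_intervals(self.exons))
        object.__setattr__(self, "exons", merged)
        for s, e in merged:
            if s < self.gene_start or e > self.gene_end:
                raise ValidationError(
                    f"{self.gene_name}: exon ({s}, {e}) outside gene span"
                )

    @property
    def span(self) -> int:
        return self.gene_end - self.gene_start + 1


class NearestGene(NamedTuple):
    gene: str | None
    distance: int | None  # 0 when overlapping, None when no candidate


class GeneTrack:
    """Gene models for one genome build, indexed for interval queries."""

    def __init__(self, genes: Iterable[GeneModel], build: str = "GRCh38"):
        self.build = build
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (CHROM_RANK.get(g.chrom, 99), g.gene_start, g.gene_name)
        )
        seen: set[tuple[str, int, str]] = set()
        for g in self.genes:
            key = (g.chrom, g.gene_start, g.gene_name)
            if key in seen:
                raise ValidationError(f"duplicate gene {g.gene_name} at {g.chrom}:{g.gene_start}")
            seen.add(key)
        self._by_name: dict[str, GeneModel] = {}
        for g in self.genes:
            self._by_name.setdefault(g.gene_name.upper(), g)
        self._index: dict[tuple[str, bool], dict] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def chromosomes(self) -> list[str]:
        present = {g.chrom for g in self.genes}
        return sorted(present, key=lambda c: CHROM_RANK.get(c, 99))

    def by_name(self, gene_name: str) -> GeneModel:
        """Case-insensitive gene lookup; unknown symbols raise with suggestions."""
        g = self._by_name.get(gene_name.upper())
        if g is None:
            close = difflib.get_close_matches(
                gene_name.upper(), list(self._by_name), n=3, cutoff=0.6
            )
            raise GeneNotFoundError(gene_name, close)
        return g

    def genes_in_region(
        self, chrom: str, start: int, end: int, protein_coding_only: bool = False
    ) -> list[GeneModel]:
        """Genes whose span intersects [start, end], position-sorted."""
        idx = self._chrom_index(chrom, protein_coding_only)
        if idx is None:
            return []
        hits = idx["tree"].overlap(start, end + 1)
        return sorted((iv.data for iv in hits), key=lambda g: (g.gene_start, g.gene_name))

    # -- nearest-gene machinery -------------------------------------------

    def _chrom_index(self, chrom: str, protein_coding_only: bool):
        key = (chrom, protein_coding_only)
        if key not in self._index:
            cands = [
                g
                for g in self.genes
                if g.chrom == chrom
                and (not protein_coding_only or g.biotype == "protein_coding")
            ]
            if not cands:
                self._index[key] = None
            else:
                tree = IntervalTree()
                for g in cands:
                    tree.addi(g.gene_start, g.gene_end + 1, g)  # half-open for the tree
                by_end = sorted(cands, key=lambda g: g.gene_end)
                by_start = sorted(cands, key=lambda g: g.gene_start)
                self._index[key] = {
                    "tree": tree,
                    "genes": cands,
                    "ends": np.array([g.gene_end for g in by_end]),
                    "by_end": by_end,
                    "starts": np.array([g.gene_start for g in by_start]),
                    "by_start": by_start,
                }
        return self._index[key]


def nearest_gene(
    chrom: str,
    pos: int,
    track: GeneTrack,
    protein_coding_only: bool = True,
) -> NearestGene:
    """The gene overlapping ``pos``, else the gene with the nearest boundary.

    Returns ``NearestGene(None, None)`` when the chromosome carries no
    candidate genes (after the biotype filter) rather than raising.
    """
    chrom = canonical_chrom(chrom) or str(chrom)
    idx = track._chrom_index(chrom, protein_coding_only)
    if idx is None:
        return NearestGene(None, None)

    hits = idx["tree"].at(pos)
    if hits:
        best = min((iv.data for iv in hits), key=lambda g: (g.span, g.gene_name))
        return NearestGene(best.gene_name, 0)

    # best gene fully left of pos (max end) and fully right (min start)
    ends, starts = idx["ends"], idx["starts"]
    candidates: list[tuple[int, str]] = []
    i = int(np.searchsorted(ends, pos)) - 1
    if i >= 0:
        candidates.append((pos - int(ends[i]), "left"))
    j = int(np.searchsorted(starts, pos, side="right"))
    if j < len(starts):
        candidates.append((int(starts[j]) - pos, "right"))
    if not candidates:
        return NearestGene(None, None)
    dmin = min(d for d, _ in candidates)
    # gather every gene achieving dmin on either side, break ties by name
    names = [g.gene_name for g in idx["by_end"] if g.gene_end == pos - dmin]
    names += [g.gene_name for g in idx["by_start"] if g.gene_start == pos + dmin]
    return NearestGene(min(names), dmin)


def annotate_with_nearest_gene(
    variants: pd.DataFrame,
    track: GeneTrack,
    protein_coding_only: bool = True,
    column: str = "Gene_Symbol",
) -> pd.DataFrame:
    """Append a nearest-gene column to any frame carrying CHROM and POS.

    Row count and order are preserved; rows on chromosomes with no candidate
    gene receive the :data:`NO_GENE` sentinel.
    """
    missing = [c for c in ("CHROM", "POS") if c not in variants.columns]
    if missing:
        raise MissingColumnError([c.lower() for c in missing])
    out = variants.copy()
    out[column] = [
        nearest_gene(c, int(p), track, protein_coding_only).gene or NO_GENE
        for c, p in zip(variants["CHROM"], variants["POS"])
    ]
    return out


def get_gene_coords(gene_name: str, track: GeneTrack):
    """Chromosome interval of a gene (case-insensitive symbol lookup)."""
    from .regions import Region  # local import to avoid a cycle

    g = track.by_name(gene_name)
    return Region(g.chrom, g.gene_start, g.gene_end, provenance="gene", label=g.gene_name)


# -- track I/O -------------------------------------------------------------

_TRACK_COLUMNS = [
    "build",
    "chrom",
    "gene_start",
    "gene_end",
    "gene_name",
    "biotype",
    "exon_starts",
    "exon_ends",
]


def write_gene_track(track: GeneTrack, path: str | Path) -> None:
    """Write the tab-delimited gene-track dialect."""
    rows = []
    for g in track.genes:
        rows.append(
            {
                "build": track.build,
                "chrom": g.chrom,
                "gene_start": g.gene_start,
                "gene_end": g.gene_end,
                "gene_name": g.gene_name,
                "biotype": g.biotype,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            }
        )
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_int_list(text) -> list[int]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    return [int(tok) for tok in str(text).rstrip(",").split(",") if tok]


def load_gene_track(path: str | Path) -> GeneTrack:
    """Load a gene track from the TSV dialect or from a GTF file.

    GTF input is restricted to ``gene`` and ``exon`` features and must carry
    ``gene_name`` attributes.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#") or len(first.split("\t")) == 9:
        return _load_gtf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_TRACK_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValidationError(f"gene track missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        starts = _parse_int_list(getattr(row, "exon_starts", ""))
        ends = _parse_int_list(getattr(row, "exon_ends", ""))
        genes.append(
            GeneModel(
                gene_name=row.gene_name,
                chrom=canonical_chrom(row.chrom) or str(row.chrom),
                gene_start=int(row.gene_start),
                gene_end=int(row.gene_end),
                biotype=row.biotype,
                exons=tuple(zip(starts, ends)),
            )
        )
    build = str(df["build"].iloc[0]) if len(df) else "GRCh38"
    return GeneTrack(genes, build=build)


def _gtf_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _load_gtf(path: Path) -> GeneTrack:
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                continue
            chrom, _, feature, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            if feature not in ("gene", "exon"):
                continue
            attrs = _gtf_attributes(fields[8])
            name = attrs.get("gene_name") or attrs.get("gene_id")
            if name is None:
                continue
            chrom = canonical_chrom(chrom) or chrom
            if feature == "gene":
                spans[name] = {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "biotype": attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding")),
                }
            else:
                exons.setdefault(name, []).append((int(start), int(end)))
    genes = [
        GeneModel(
            gene_name=name,
            chrom=info["chrom"],
            gene_start=info["start"],
            gene_end=info["end"],
            biotype=info["biotype"],
            exons=tuple(exons.get(name, ())),
        )
        for name, info in spans.items()
    ]
    return GeneTrack(genes)
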