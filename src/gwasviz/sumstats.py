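"""Reading, validating and canonicalising GWAS summary-statistics tables.

Summary statistics arrive as delimited text with one row per variant and
loosely standardised column names (``chr``/``CHROM``/``chromosome``,
``pval``/``P`` ...).  This module resolves those aliases case-insensitively,
validates the three mandatory roles (chromosome, position, p-value) and
produces a canonical, chromosome/position-sorted table with fixed column
names so every downstream operation can rely on a single schema.

Canonical columns: CHROM (str, no "chr" prefix), POS (int, 1-based), P
(float in (0, 1]), and optionally ID, REF, ALT, BETA, OR, R2, GENE.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AmbiguousColumnError, MissingColumnError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical chromosome labels in Manhattan display order.
CHROM_ORDER = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}

#: Smallest positive double; p-values of exactly 0 are clamped here so the
#: -log10 transform stays finite.
TINY_P = np.nextafter(0.0, 1.0)

# role -> accepted (lower-cased) header aliases
_ALIASES = {
    "chrom": {"chr", "chrom", "chromosome"},
    "pos": {"pos", "bp", "base_pair_location", "position"},
    "p": {"p", "pval", "p_value", "pvalue"},
    "id": {"id", "rsid", "snp", "variant_id"},
    "ref": {"ref", "reference", "ref_allele", "other_allele"},
    "alt": {"alt", "alternative", "alt_allele", "effect_allele"},
    "beta": {"beta"},
    "or": {"or", "odds_ratio"},
    "r2": {"r2", "rsq"},
    "gene": {"gene", "gene_symbol", "gene_name"},
}

_MANDATORY = ("chrom", "pos", "p")

# role -> canonical column name in a GwasDataset frame
ROLE_TO_COLUMN = {
    "chrom": "CHROM",
    "pos": "POS",
    "p": "P",
    "id": "ID",
    "ref": "REF",
    "alt": "ALT",
    "beta": "BETA",
    "or": "OR",
    "r2": "R2",
    "gene": "GENE",
}


@dataclass(frozen=True)
class ColumnMap:
    """Resolved source column name per role (``None`` when absent)."""

    chrom: str
    pos: str
    p: str
    id: str | None = None
    ref: str | None = None
    alt: str | None = None
    beta: str | None = None
    odds_ratio: str | None = None
    r2: str | None = None
    gene: str | None = None

    @property
    def effect(self) -> str | None:
        """The designated effect-size source: BETA wins over OR."""
        return self.beta if self.beta is not None else self.odds_ratio


def infer_columns(header: list[str]) -> ColumnMap:
    """Resolve a header into column roles, case-insensitively.

    Raises
    ------
    MissingColumnError
        if any of the chromosome / position / p-value roles is absent.
    AmbiguousColumnError
        if two header columns resolve to the same role.
    """
    if not header:
        raise ValidationError("empty header")
    found: dict[str, str] = {}
    for role, aliases in _ALIASES.items():
        hits = [col for col in header if col.strip().lower() in aliases]
        if len(hits) > 1:
            raise AmbiguousColumnError(role, hits)
        if hits:
            found[role] = hits[0]
    missing = [r for r in _MANDATORY if r not in found]
    if missing:
        raise MissingColumnError(missing)
    if "beta" in found and "or" in found:
        logger.warning(
            "both BETA (%s) and OR (%s) columns present; BETA is used as the "
            "effect source and OR is ignored",
            found["beta"],
            found["or"],
        )
    return ColumnMap(
        chrom=found["chrom"],
        pos=found["pos"],
        p=found["p"],
        id=found.get("id"),
        ref=found.get("ref"),
        alt=found.get("alt"),
        beta=found.get("beta"),
        odds_ratio=found.get("or"),
        r2=found.get("r2"),
        gene=found.get("gene"),
    )


def canonical_chrom(value) -> str | None:
    """Normalise a chromosome label; ``None`` when not a canonical contig."""
    s = str(value).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    if s.startswith("0") and s[1:] in CHROM_RANK:  # "01" style padding
        s = s.lstrip("0")
    return s if s in CHROM_RANK else None


@dataclass
class GwasDataset:
    """A validated summary-statistics table plus a dataset label.

    ``df`` always carries CHROM/POS/P with canonical values, is sorted by
    (chromosome rank, position), and may carry ID/REF/ALT/BETA/OR/R2/GENE.
    ``dropped`` counts rows removed at validation, keyed by reason.
    """

    df: pd.DataFrame
    label: str = "GWAS"
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.label:
            raise ValidationError("dataset label must be non-empty")
        for col in ("CHROM", "POS", "P"):
            if col not in self.df.columns:
                raise MissingColumnError([col.lower()])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosomes present, in canonical order."""
        present = set(self.df["CHROM"])
        return [c for c in CHROM_ORDER if c in present]

    def effect(self) -> pd.Series:
        """Effect sizes on the beta (log-odds) scale.

        Uses BETA when present; otherwise converts OR via the natural log.
        """
        if "BETA" in self.df.columns:
            return self.df["BETA"].astype(float)
        if "OR" in self.df.columns:
            odds = self.df["OR"].astype(float)
            if (odds <= 0).any():
                raise ValidationError("odds ratios must be > 0 to convert to beta")
            return pd.Series(np.log(odds), index=self.df.index, name="BETA")
        raise MissingColumnError(["beta/or"])

    def subset(self, mask_or_frame, label: str | None = None) -> "GwasDataset":
        df = (
            mask_or_frame
            if isinstance(mask_or_frame, pd.DataFrame)
            else self.df[mask_or_frame]
        )
        return replace(self, df=df.copy(), label=label or self.label, dropped={})


def from_frame(
    raw: pd.DataFrame,
    label: str = "GWAS",
    colmap: ColumnMap | None = None,
) -> GwasDataset:
    """Canonicalise an arbitrary summary-statistics frame into a GwasDataset.

    Column roles are inferred from the header unless ``colmap`` is given.
    Rows failing validation (unparseable position or p-value, p outside
    (0, 1], position < 1, non-canonical chromosome) are dropped and counted;
    p-values of exactly 0 are clamped to the smallest positive double.
    """
    if raw.empty and raw.columns.empty:
        raise ValidationError("empty table")
    cm = colmap or infer_columns(list(raw.columns))

    out = pd.DataFrame(index=raw.index)
    out["CHROM"] = raw[cm.chrom].map(canonical_chrom)
    out["POS"] = pd.to_numeric(raw[cm.pos], errors="coerce")
    out["P"] = pd.to_numeric(raw[cm.p], errors="coerce")
    optional = {
        "ID": cm.id,
        "REF": cm.ref,
        "ALT": cm.alt,
        "BETA": cm.beta,
        "OR": cm.odds_ratio,
        "R2": cm.r2,
        "GENE": cm.gene,
    }
    for canon, src in optional.items():
        if src is not None:
            if canon in ("BETA", "OR", "R2"):
                out[canon] = pd.to_numeric(raw[src], errors="coerce")
            else:
                out[canon] = raw[src].astype(str)
    if "REF" in out.columns:
        out["REF"] = out["REF"].str.upper()
    if "ALT" in out.columns:
        out["ALT"] = out["ALT"].str.upper()

    dropped: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str):
        nonlocal out
        n = int(mask.sum())
        if n:
            dropped[reason] = dropped.get(reason, 0) + n
            out = out[~mask]

    _drop(out["CHROM"].isna(), "non-canonical chromosome")
    _drop(out["POS"].isna(), "unparseable position")
    _drop(out["POS"] < 1, "position < 1")
    _drop(out["P"].isna(), "unparseable p-value")
    _drop((out["P"] < 0) | (out["P"] > 1), "p-value outside [0, 1]")

    n_zero = int((out["P"] == 0).sum())
    if n_zero:
        logger.warning("clamped %d zero p-value(s) to the smallest positive double", n_zero)
        out.loc[out["P"] == 0, "P"] = TINY_P
    if "R2" in out.columns:
        bad_r2 = out["R2"].notna() & ((out["R2"] < 0) | (out["R2"] > 1))
        _drop(bad_r2, "r2 outside [0, 1]")

    out["POS"] = out["POS"].astype(np.int64)
    rank = out["CHROM"].map(CHROM_RANK)
    out = (
        out.assign(_rank=rank)
        .sort_values(["_rank", "POS"], kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    for reason, n in dropped.items():
        logger.warning("%s: dropped %d row(s): %s", label, n, reason)
    return GwasDataset(df=out, label=label, dropped=dropped)


def _sniff_delimiter(sample: str) -> str | None:
    """Pick tab, comma or whitespace from the first line of a file."""
    first = sample.splitlines()[0] if sample else ""
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return None  # any-whitespace


def read_sumstats(
    path: str | Path,
    delimiter: str | None = None,
    label: str | None = None,
) -> GwasDataset:
    """Read a delimited summary-statistics file into a canonical GwasDataset.

    The delimiter is auto-detected among tab / comma / whitespace unless
    given.  The first line must be a header; rows failing validation are
    dropped with a logged count per reason.
    """
    path = Path(path)
    text_head = path.open().readline()
    if not text_head.strip():
        raise ValidationError(f"{path}: empty file")
    sep = delimiter if delimiter is not None else _sniff_delimiter(text_head)
    kwargs = {"sep": sep} if sep is not None else {"sep": r"\s+"}
    raw = pd.read_csv(path, dtype=str, **kwargs)
    return from_frame(raw, label=label or path.stem)


def write_sumstats(data: GwasDataset, path: str | Path) -> None:
    """Write the canonical table as TSV (round-trips through read_sumstats)."""
    data.df.to_csv(path, sep="\t", index=False)


def parse_chrom_list(text: str) -> list[str]:
    """Split a user-supplied chromosome list like ``"1,2,X"``."""
    chroms = [canonical_chrom(tok) for tok in re.split(r"[,\s]+", text) if tok]
    if any(c is None for c in chroms):
        raise ValidationError(f"non-canonical chromosome in {text!r}")
    return chroms
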