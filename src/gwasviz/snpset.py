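"""Cross-dataset variant matching, allele harmonisation and effect flipping.

Comparing effect sizes between two GWAS requires the same variant, measured
against the same allele, in both datasets.  The pipeline here builds a
*snpset* from two datasets D1 and D2:

1. extract the lead variants of D1 (greedy windowed selection);
2. match them to D2 rows by (chromosome, position);
3. reconcile alleles: an exact REF/ALT match is kept as-is; a swapped match
   (REF1 = ALT2 and ALT1 = REF2) is kept after negating the D2 effect and
   swapping its alleles; anything else is set aside as "no allele match";
4. orient every row to the allele with a positive D1 effect: rows with
   E1 < 0 have both effects negated and both (harmonised) allele pairs
   swapped.

Strand-ambiguous pairs (A/T vs T/A, C/G vs G/C) are handled by the literal
swap rule only — no reverse-complement matching is attempted, since silent
strand flips are a known error source.

The three outputs partition the D1 leads exactly:
``len(leads) == len(snpset) + len(not_found) + len(no_allele_match)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingColumnError, ValidationError
from .regions import DEFAULT_REGION_SIZE, DEFAULT_THRESH, get_lead_snps
from .sumstats import GwasDataset

logger = logging.getLogger(__name__)

#: Genome-wide significance used for the dataset-2 significance flag.
GENOME_WIDE_P = 5e-8

#: The effect-comparison schema (plus CHROM, POS and an optional gene).
SNPSET_COLUMNS = ["P1", "E1", "ALT1", "REF1", "P2", "E2", "ALT2", "REF2"]


def or_to_beta(or_value):
    """Convert odds ratio(s) to beta(s) via the natural logarithm."""
    arr = np.asarray(or_value, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("odds ratios must be > 0")
    out = np.log(arr)
    return float(out) if np.isscalar(or_value) or arr.ndim == 0 else out


def _with_effect(df: pd.DataFrame, who: str) -> pd.DataFrame:
    """Materialise a BETA column, converting OR when BETA is absent."""
    df = df.copy()
    if "BETA" in df.columns:
        return df
    if "OR" in df.columns:
        df["BETA"] = or_to_beta(df["OR"].to_numpy())
        return df
    raise MissingColumnError([f"{who} effect (beta/or)"])


def _require_alleles(df: pd.DataFrame, who: str) -> None:
    missing = [c for c in ("REF", "ALT") if c not in df.columns]
    if missing:
        raise MissingColumnError([f"{who} {c.lower()}" for c in missing])


@dataclass
class SnpSetReport:
    """Three-way partition of dataset-1 leads after matching against D2."""

    snpset: pd.DataFrame  # harmonised, positively-oriented rows
    not_found: pd.DataFrame  # D1 leads with no positional partner in D2
    no_allele_match: pd.DataFrame  # positional partners, irreconcilable alleles

    def __post_init__(self):
        n = len(self.snpset) + len(self.not_found) + len(self.no_allele_match)
        self.n_leads = n

    def summary(self) -> str:
        return (
            f"{len(self.snpset)} matched, {len(self.not_found)} not found by "
            f"position, {len(self.no_allele_match)} with no allele match "
            f"(of {self.n_leads} leads)"
        )


def match_by_pos(
    d1_leads: pd.DataFrame, d2: GwasDataset | pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair D1 leads with every D2 row sharing (CHROM, POS).

    Returns ``(pairs, not_found)``.  ``pairs`` carries one row per
    (lead, partner) combination with columns CHROM, POS, optional ID,
    REF1/ALT1/P1/E1 and REF2/ALT2/P2/E2, plus ``_lead`` identifying the
    originating lead row.  ``not_found`` keeps the original D1 columns.
    """
    d2f = d2.df if isinstance(d2, GwasDataset) else d2
    leads = d1_leads.reset_index(drop=True).copy()
    leads["_lead"] = leads.index

    left = leads.rename(
        columns={"REF": "REF1", "ALT": "ALT1", "P": "P1", "BETA": "E1"}
    )
    keep1 = [c for c in ("CHROM", "POS", "ID", "REF1", "ALT1", "P1", "E1", "_lead") if c in left.columns]
    right = d2f.rename(columns={"REF": "REF2", "ALT": "ALT2", "P": "P2", "BETA": "E2"})
    keep2 = [c for c in ("CHROM", "POS", "REF2", "ALT2", "P2", "E2") if c in right.columns]

    pairs = left[keep1].merge(right[keep2], on=["CHROM", "POS"], how="left", indicator=True)
    unmatched_leads = pairs.loc[pairs["_merge"] == "left_only", "_lead"].unique()
    pairs = pairs[pairs["_merge"] == "both"].drop(columns="_merge")
    not_found = leads[leads["_lead"].isin(unmatched_leads)].drop(columns="_lead")
    return pairs.reset_index(drop=True), not_found.reset_index(drop=True)


def match_by_alleles(
    pairs: pd.DataFrame, d1_leads: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconcile REF/ALT between the paired datasets.

    Exact matches are kept unchanged; swapped matches have the D2 effect
    negated and D2 alleles swapped.  A lead none of whose partners can be
    reconciled goes to ``no_allele_match`` (original D1 columns when
    ``d1_leads`` is provided, else the pair rows).  If several partners of
    one lead harmonise (duplicate D2 rows), the first in position-sorted
    order is kept with a warning.
    """
    for col in ("REF1", "ALT1", "REF2", "ALT2"):
        if col not in pairs.columns:
            raise MissingColumnError([col.lower()])
    pairs = pairs.reset_index(drop=True).copy()
    if "_lead" not in pairs.columns:
        pairs["_lead"] = pairs.index

    exact = (pairs["REF1"] == pairs["REF2"]) & (pairs["ALT1"] == pairs["ALT2"])
    swapped = (pairs["REF1"] == pairs["ALT2"]) & (pairs["ALT1"] == pairs["REF2"]) & ~exact
    ok = exact | swapped

    harm = pairs[ok].copy()
    if swapped.any():
        idx = harm.index[swapped[ok].to_numpy()]
        harm.loc[idx, "E2"] = -harm.loc[idx, "E2"]
        harm.loc[idx, ["REF2", "ALT2"]] = harm.loc[idx, ["ALT2", "REF2"]].to_numpy()

    dup = harm.duplicated(subset="_lead", keep=False)
    if dup.any():
        logger.warning(
            "%d lead(s) harmonise with more than one dataset-2 row; "
            "keeping the first in position-sorted order",
            harm.loc[dup, "_lead"].nunique(),
        )
        harm = harm.sort_values(["CHROM", "POS"], kind="stable").drop_duplicates(
            subset="_lead", keep="first"
        )
    harm = harm.sort_values("_lead", kind="stable")

    matched_leads = set(harm["_lead"])
    lost = pairs[~pairs["_lead"].isin(matched_leads)].drop_duplicates(subset="_lead")
    if d1_leads is not None:
        src = d1_leads.reset_index(drop=True)
        no_match = src.loc[sorted(lost["_lead"])].reset_index(drop=True)
    else:
        no_match = lost.reset_index(drop=True)
    return harm.reset_index(drop=True), no_match


def flip_to_positive_allele_for_dat1(rows: pd.DataFrame) -> pd.DataFrame:
    """Orient each harmonised row to the positively-associated D1 allele.

    Rows with E1 < 0 get both effects negated and both allele pairs swapped
    (keeping D1/D2 harmonised); E1 = 0 counts as non-negative and is left
    untouched.  Applying the transform twice is the identity.
    """
    out = rows.copy()
    neg = out["E1"] < 0
    if neg.any():
        out.loc[neg, ["E1", "E2"]] = -out.loc[neg, ["E1", "E2"]]
        out.loc[neg, ["REF1", "ALT1"]] = out.loc[neg, ["ALT1", "REF1"]].to_numpy()
        out.loc[neg, ["REF2", "ALT2"]] = out.loc[neg, ["ALT2", "REF2"]].to_numpy()
    return out


def _order_snpset(df: pd.DataFrame) -> pd.DataFrame:
    lead_cols = ["CHROM", "POS"] + (["ID"] if "ID" in df.columns else [])
    extra = [c for c in df.columns if c not in lead_cols + SNPSET_COLUMNS + ["_lead"]]
    cols = lead_cols + SNPSET_COLUMNS + extra
    return df[[c for c in cols if c in df.columns]]


def get_snpset(
    d1: GwasDataset,
    d2: GwasDataset,
    thresh: float = DEFAULT_THRESH,
    region_size: int = DEFAULT_REGION_SIZE,
    verbose: bool = False,
):
    """Build the effect-comparison snpset from two datasets.

    Composes lead extraction on D1, positional matching against D2, allele
    reconciliation and positive-allele orientation; odds ratios are
    converted to betas first.  With ``verbose=True`` returns the full
    :class:`SnpSetReport`; otherwise just the snpset table.
    """
    _require_alleles(d1.df, "dataset 1")
    _require_alleles(d2.df, "dataset 2")
    df1 = _with_effect(d1.df, "dataset 1")
    df2 = _with_effect(d2.df, "dataset 2")

    leads = get_lead_snps(df1, thresh=thresh, region_size=region_size)
    pairs, not_found = match_by_pos(leads, df2)
    harm, no_allele = match_by_alleles(pairs, d1_leads=leads)
    snp = _order_snpset(flip_to_positive_allele_for_dat1(harm).drop(columns="_lead"))
    report = SnpSetReport(
        snpset=snp.reset_index(drop=True),
        not_found=not_found,
        no_allele_match=no_allele,
    )
    return report if verbose else report.snpset


def effect_table(
    d1: GwasDataset | None = None,
    d2: GwasDataset | None = None,
    snpset: pd.DataFrame | None = None,
    track=None,
    thresh: float = DEFAULT_THRESH,
    region_size: int = DEFAULT_REGION_SIZE,
    sign_thresh2: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """The table behind the effect-comparison plot.

    One row per snpset entry with a ``gene`` label (taken from an existing
    GENE/gene column, else the nearest gene when a track is given, else the
    variant ID / coordinates) and a boolean ``significant2`` flag for
    ``P2 < sign_thresh2``.
    """
    if snpset is None:
        if d1 is None or d2 is None:
            raise ValidationError("supply either two datasets or a snpset")
        snpset = get_snpset(d1, d2, thresh=thresh, region_size=region_size)
    out = snpset.copy()
    for col in SNPSET_COLUMNS:
        if col not in out.columns:
            raise MissingColumnError([col.lower()])
    if "gene" not in out.columns:
        if "GENE" in out.columns:
            out["gene"] = out["GENE"]
        elif track is not None and len(out):
            from .genes import annotate_with_nearest_gene

            out = annotate_with_nearest_gene(out, track, column="gene")
        elif "ID" in out.columns:
            out["gene"] = out["ID"]
        else:
            out["gene"] = [
                f"{c}:{p}" for c, p in zip(out.get("CHROM", []), out.get("POS", []))
            ]
    out["significant2"] = out["P2"] < sign_thresh2
    return out


def write_snpset(snpset: pd.DataFrame, path) -> None:
    """Write a snpset as TSV in the canonical column order."""
    _order_snpset(snpset).to_csv(path, sep="\t", index=False)
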