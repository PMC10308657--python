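"""Reproducible synthetic GWAS summary statistics and gene tracks.

The generators here emulate the shape of real summary statistics well
enough to exercise every operation in the package — planted association
peaks for lead selection and labelling, a consistent gene track for
annotation queries, and derived second cohorts for the matching /
harmonisation pipeline — without any population-genetic realism: peaks are
deterministic linear decays of -log10(p) around an apex, not LD blocks,
and background p-values are uniform, as under a pure null.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genes import GeneModel, GeneTrack
from .sumstats import CHROM_RANK, GwasDataset

logger = logging.getLogger(__name__)

#: Small default genome: big enough for multi-chromosome layout, small
#: enough that every test runs in milliseconds.
DEFAULT_CHROM_LENGTHS = {"1": 10_000_000, "2": 8_000_000, "3": 6_000_000, "X": 5_000_000}

#: Unambiguous allele pairs (neither A/T nor C/G, which are strand-ambiguous).
_SAFE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class PeakSpec:
    """A planted association peak.

    -log10(p) decays linearly from ``-log10(min_p)`` at ``center_pos`` to 0
    over ``width`` bp on each side; ``n_variants`` variants are spread over
    the peak, and effect sizes are drawn around ``effect`` with a sign
    consistent across the peak.
    """

    chrom: str
    center_pos: int
    min_p: float = 1e-12
    width: int = 200_000
    n_variants: int = 25
    effect: float = 0.3
    alleles: tuple[str, str] = ("A", "G")

    def __post_init__(self):
        if not (0 < self.min_p < 1):
            raise ValidationError(f"min_p must lie in (0, 1), got {self.min_p}")
        if self.width <= 0:
            raise ValidationError("peak width must be positive")
        if self.n_variants < 1:
            raise ValidationError("a peak needs at least one variant")


def default_peaks(k: int, chrom_lengths=None, spacing: int = 1_500_000) -> list[PeakSpec]:
    """``k`` disjoint peaks spread across the genome, > 1 Mb apart."""
    lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    chroms = sorted(lengths, key=lambda c: CHROM_RANK.get(c, 99))
    peaks = []
    ci, pos = 0, spacing
    for i in range(k):
        while pos + spacing > lengths[chroms[ci]]:
            ci = (ci + 1) % len(chroms)
            pos = spacing
        peaks.append(
            PeakSpec(
                chrom=chroms[ci],
                center_pos=pos,
                effect=0.2 + 0.05 * i,
                alleles=_SAFE_PAIRS[i % len(_SAFE_PAIRS)],
            )
        )
        pos += spacing
    return peaks


def simulate_sumstats(
    n_background: int = 5000,
    chrom_lengths: dict[str, int] | None = None,
    peaks: list[PeakSpec] | None = None,
    seed: int = 0,
    label: str = "simulated",
    effect_sd: float = 0.02,
    ambiguous_alleles: bool = False,
) -> GwasDataset:
    """Background variants under the uniform null plus planted peaks.

    Background p-values are Uniform(0, 1) with positions uniform over each
    chromosome (proportional allocation); peak variants follow the linear
    -log10(p) decay of their :class:`PeakSpec`.  REF/ALT are sampled from
    strand-unambiguous pairs unless ``ambiguous_alleles`` is set.
    Deterministic for a fixed seed.
    """
    lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    if any(v <= 0 for v in lengths.values()):
        raise ValidationError("chromosome lengths must be positive")
    peaks = list(peaks or [])
    _warn_on_overlap(peaks)
    rng = np.random.default_rng(seed)

    records = []
    total = sum(lengths.values())
    pair_pool = _SAFE_PAIRS + (_AMBIGUOUS_PAIRS if ambiguous_alleles else [])
    for chrom, length in lengths.items():
        n = int(round(n_background * length / total))
        pos = rng.integers(1, length + 1, size=n)
        pvals = rng.uniform(0.0, 1.0, size=n)
        pair_idx = rng.integers(0, len(pair_pool), size=n)
        betas = rng.normal(0.0, effect_sd, size=n)
        for j in range(n):
            ref, alt = pair_pool[pair_idx[j]]
            records.append((chrom, int(pos[j]), float(np.clip(pvals[j], 1e-300, 1.0)), ref, alt, float(betas[j])))

    for peak in peaks:
        apex_mlp = -np.log10(peak.min_p)
        if peak.n_variants == 1:
            offsets = np.array([0.0])
        else:
            offsets = np.linspace(-peak.width, peak.width, peak.n_variants)
        sign = 1.0 if peak.effect >= 0 else -1.0
        for off in offsets:
            frac = 1.0 - abs(off) / peak.width
            mlp = apex_mlp * frac
            p = float(10.0 ** (-mlp))
            beta = sign * max(
                abs(peak.effect) * frac, 0.01
            ) + float(rng.normal(0.0, effect_sd * 0.1))
            pos = int(round(peak.center_pos + off))
            records.append(
                (peak.chrom, max(1, pos), min(max(p, 1e-300), 1.0), *peak.alleles, beta)
            )

    df = pd.DataFrame(
        records, columns=["CHROM", "POS", "P", "REF", "ALT", "BETA"]
    )
    df["ID"] = [
        f"rs{chrom}_{pos}" for chrom, pos in zip(df["CHROM"], df["POS"])
    ]
    rank = df["CHROM"].map(CHROM_RANK)
    df = (
        df.assign(_rank=rank)
        .sort_values(["_rank", "POS"], kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return GwasDataset(df=df[["CHROM", "POS", "P", "ID", "REF", "ALT", "BETA"]], label=label)


def _warn_on_overlap(peaks: list[PeakSpec]) -> None:
    by_chrom: dict[str, list[PeakSpec]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        ps = sorted(ps, key=lambda p: p.center_pos)
        for a, b in zip(ps, ps[1:]):
            if b.center_pos - a.center_pos < a.width + b.width:
                logger.warning(
                    "peaks at %s:%d and %s:%d overlap", chrom, a.center_pos, chrom, b.center_pos
                )


def simulate_gene_track(
    chrom_lengths: dict[str, int] | None = None,
    n_genes: int = 40,
    seed: int = 0,
    build: str = "synthetic",
) -> GeneTrack:
    """A synthetic gene track with non-pathological gene models.

    Genes span 5-200 kb with 2-10 internal non-overlapping exons, are
    spread proportionally over the chromosomes, and are named GENE1..GENEn
    in coordinate order.  Deterministic per seed.
    """
    lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    rng = np.random.default_rng(seed)
    total = sum(lengths.values())
    genes: list[GeneModel] = []
    gid = 1
    for chrom, length in lengths.items():
        n = max(1, int(round(n_genes * length / total)))
        starts = np.sort(rng.integers(1, max(2, length - 200_000), size=n))
        for s in starts:
            span = int(rng.integers(5_000, 200_001))
            start, end = int(s), min(int(s) + span, length)
            n_ex = int(rng.integers(2, 11))
            bounds = np.sort(rng.choice(np.arange(start, end + 1), size=min(2 * n_ex, end - start + 1), replace=False))
            exons = tuple(
                (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(len(bounds) // 2)
            )
            genes.append(
                GeneModel(
                    gene_name=f"GENE{gid}",
                    chrom=chrom,
                    gene_start=start,
                    gene_end=end,
                    biotype="protein_coding" if rng.uniform() < 0.8 else "lincRNA",
                    exons=exons,
                )
            )
            gid += 1
    return GeneTrack(genes, build=build)


@dataclass
class CohortTruth:
    """Per-row ground truth of the manipulations applied by paired_cohorts."""

    dropped_pos: set = field(default_factory=set)  # (chrom, pos) removed
    corrupted_pos: set = field(default_factory=set)  # alleles made irreconcilable
    flipped_pos: set = field(default_factory=set)  # REF/ALT swapped, effect negated


def paired_cohorts(
    base: GwasDataset,
    drop_frac: float = 0.0,
    allele_corrupt_frac: float = 0.0,
    flip_frac: float = 0.0,
    effect_noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "cohort2",
) -> tuple[GwasDataset, CohortTruth]:
    """Derive a second cohort from ``base`` with known manipulations.

    A fraction of positions is dropped (-> "not found"), a fraction gets
    irreconcilable alleles (-> "no allele match"), a fraction gets REF/ALT
    swapped with the effect negated (-> exercises the flip rule), and
    Gaussian noise is added to the effects.  The returned
    :class:`CohortTruth` records exactly which positions were touched.
    """
    for name, frac in (
        ("drop_frac", drop_frac),
        ("allele_corrupt_frac", allele_corrupt_frac),
        ("flip_frac", flip_frac),
    ):
        if not (0.0 <= frac <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {frac}")
    for col in ("REF", "ALT", "BETA"):
        if col not in base.df.columns:
            raise ValidationError(f"paired_cohorts needs a {col} column in the base dataset")

    rng = np.random.default_rng(seed)
    df = base.df.copy().reset_index(drop=True)
    n = len(df)
    truth = CohortTruth()

    perm = rng.permutation(n)
    n_drop = int(round(drop_frac * n))
    n_corrupt = int(round(allele_corrupt_frac * n))
    n_flip = int(round(flip_frac * n))
    drop_idx = perm[:n_drop]
    corrupt_idx = perm[n_drop : n_drop + n_corrupt]
    flip_idx = perm[n_drop + n_corrupt : n_drop + n_corrupt + n_flip]

    key = list(zip(df["CHROM"], df["POS"]))
    truth.dropped_pos = {key[i] for i in drop_idx}
    truth.corrupted_pos = {key[i] for i in corrupt_idx}
    truth.flipped_pos = {key[i] for i in flip_idx}

    bases = ("A", "C", "G", "T")
    for i in corrupt_idx:
        ref, alt = df.at[i, "REF"], df.at[i, "ALT"]
        # pick an ALT that matches neither allele: irreconcilable by construction
        df.at[i, "ALT"] = next(b for b in bases if b not in (ref, alt))
    if len(flip_idx):
        ref = df.loc[flip_idx, "REF"].to_numpy()
        df.loc[flip_idx, "REF"] = df.loc[flip_idx, "ALT"].to_numpy()
        df.loc[flip_idx, "ALT"] = ref
        df.loc[flip_idx, "BETA"] = -df.loc[flip_idx, "BETA"]
    if effect_noise_sd > 0:
        df["BETA"] = df["BETA"] + rng.normal(0.0, effect_noise_sd, size=n)
    if len(drop_idx):
        df = df.drop(index=drop_idx).reset_index(drop=True)
    return GwasDataset(df=df, label=label), truth
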