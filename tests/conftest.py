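import numpy as np
import pandas as pd
import pytest

from gwasviz import (
    GeneModel,
    GeneTrack,
    GwasDataset,
    default_peaks,
    simulate_gene_track,
    simulate_sumstats,
)


def make_dataset(rows, label="test", **extra_cols):
    """Build a GwasDataset from (chrom, pos, p[, ...]) tuples or a dict."""
    if isinstance(rows, dict):
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(rows, columns=["CHROM", "POS", "P"])
    for k, v in extra_cols.items():
        df[k] = v
    df["CHROM"] = df["CHROM"].astype(str)
    df["POS"] = df["POS"].astype(np.int64)
    from gwasviz.sumstats import CHROM_RANK

    df = (
        df.assign(_r=df["CHROM"].map(CHROM_RANK))
        .sort_values(["_r", "POS"], kind="stable")
        .drop(columns="_r")
        .reset_index(drop=True)
    )
    return GwasDataset(df=df, label=label)


@pytest.fixture
def tiny_track():
    """Three genes on chromosome 1, one on chromosome 2."""
    return GeneTrack(
        [
            GeneModel("GENEA", "1", 100_000, 200_000, exons=((100_000, 120_000), (180_000, 200_000))),
            GeneModel("GENEB", "1", 500_000, 600_000, exons=((500_000, 510_000),)),
            GeneModel("GENEC", "1", 650_000, 660_000),
            GeneModel("GENED", "2", 1_000_000, 1_050_000),
        ],
        build="synthetic",
    )


@pytest.fixture
def sim_data():
    return simulate_sumstats(n_background=2000, peaks=default_peaks(3), seed=11)


@pytest.fixture
def sim_track():
    return simulate_gene_track(seed=11)


# ---- independent oracles (naive implementations used only in tests) ------


def oracle_lead_snps(df, thresh, region_size):
    """Brute-force greedy windowed lead selection, implemented from scratch."""
    rows = [r for r in df.to_dict("records") if r["P"] < thresh]
    leads = []
    remaining = sorted(rows, key=lambda r: (r["P"], r["POS"]))
    while remaining:
        best = remaining.pop(0)
        leads.append(best)
        remaining = [
            r
            for r in remaining
            if r["CHROM"] != best["CHROM"]
            or abs(r["POS"] - best["POS"]) >= region_size / 2
        ]
    from gwasviz.sumstats import CHROM_RANK

    return sorted(leads, key=lambda r: (CHROM_RANK[r["CHROM"]], r["POS"]))


def oracle_nearest_gene(chrom, pos, track, protein_coding_only=True):
    """Exhaustive O(n) scan over every gene on the chromosome."""
    best = None
    for g in track.genes:
        if g.chrom != chrom:
            continue
        if protein_coding_only and g.biotype != "protein_coding":
            continue
        if g.gene_start <= pos <= g.gene_end:
            d, tie = 0, (g.span, g.gene_name)
        else:
            d = min(abs(pos - g.gene_start), abs(pos - g.gene_end))
            tie = (g.gene_name,)
        cand = (d, tie, g.gene_name)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return (None, None) if best is None else (best[2], best[0])
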