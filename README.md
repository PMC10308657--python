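# gwasviz

Visualise, annotate and compare GWAS summary statistics from Python:
genome-wide Manhattan plots, regional association plots with gene/exon
tracks, LD-coloured (locuszoom-style) regional views, and effect-size
comparison plots across cohorts — plus the analysis helpers behind them:
lead-variant extraction, nearest-gene annotation, and cross-dataset variant
matching with allele harmonisation.

It is aimed at analysts who receive per-variant association results (one
row per variant with at least chromosome, position and p-value) from their
own GWAS or from public repositories, and want an annotated visual overview,
regional deep-dives, and quantitative cross-cohort comparison without
individual-level genotypes.

## The core operations

**Manhattan layout.** Each variant is drawn at cumulative genomic
coordinate `x = offset(chrom) + pos` against `-log10(p)`, where
`offset(chrom)` is the summed span of the preceding chromosomes plus a
fixed gap; alternating semi-transparent shades distinguish chromosomes and
a genome-wide significance line is drawn at `p = 5 × 10⁻⁸` by default.
Several datasets can share one upward axis, or be split top/bottom with a
mirrored (reversed) lower axis via `ntop`.

**Lead (index) variants.** `get_lead_snps(data, thresh=5e-8,
region_size=1_000_000)` greedily takes the remaining variant with the
smallest p-value below `thresh`, then excludes every variant within
`region_size/2` bp on each side — one representative per association peak.
Leads can be annotated with their nearest gene (overlap first; otherwise
smallest distance to a gene boundary, deterministic tie-breaks).

**Cross-cohort comparison (snpset).** Dataset-1 leads are matched to
dataset 2 by (chromosome, position); alleles are reconciled — identical
REF/ALT kept as-is, swapped REF/ALT kept after negating the dataset-2
effect (`β₂ → −β₂`) and swapping its alleles, anything else set aside —
and every row is oriented so the dataset-1 effect is non-negative.
Odds ratios are converted to betas (`β = ln OR`) first.  The three outputs
(`snpset`, `not_found`, `no_allele_match`) exactly partition the leads.

All plot functions return a declarative `PlotSpec` (JSON-serialisable;
points, shades, lines, labels, gene glyphs in data coordinates) which
`render()` draws with matplotlib to PNG/SVG/PDF.

## Worked example

```python
import gwasviz as gv

data  = gv.simulate_sumstats(n_background=5000, peaks=gv.default_peaks(4), seed=2)
track = gv.simulate_gene_track(seed=2)

leads = gv.get_lead_snps(data)                       # thresh=5e-8, 1 Mb window
print(gv.annotate_with_nearest_gene(leads, track)[
    ["CHROM", "POS", "P", "BETA", "Gene_Symbol"]].to_string(index=False))

spec = gv.manhattan(data, annotate=1e-9, track=track)
gv.render(spec, "manhattan.png")
```

prints

```
CHROM     POS            P     BETA Gene_Symbol
    1 1500000 1.000000e-12 0.199318       GENE3
    1 3000000 1.000000e-12 0.252746       GENE5
    1 4500000 1.000000e-12 0.300812       GENE8
    1 6000000 1.000000e-12 0.347223       GENE9
```

— one lead per planted peak, each at its apex position (`P` is the apex
p-value, `BETA` the effect at that variant) and each labelled with the
nearest gene from the synthetic track.  The rendered Manhattan plot carries
the same four labels above the significance line.

The `examples/` directory has one short script per capability (Manhattan,
lead extraction, regional plot, multi-dataset display, effect comparison,
LD-coloured regional view); each prints the numbers it computes and a line
on what they mean.

A thin CLI mirrors the library for file-based use:

```bash
gwasviz simulate --out-sumstats ss.tsv --out-track genes.tsv --seed 1
gwasviz manhattan --in ss.tsv --out man.png --track genes.tsv --annotate 1e-9
gwasviz snpset --in ss1.tsv --in ss2.tsv --out-prefix cmp --verbose
```

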