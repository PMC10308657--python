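# Methods

## Input model and canonicalisation

A summary-statistics table is one row per variant.  Three column roles are
mandatory — chromosome, position, p-value — and are resolved from common
header aliases case-insensitively (`chr`/`chrom`/`chromosome`,
`pos`/`bp`/`base_pair_location`/`position`, `p`/`pval`/`p_value`/`pvalue`);
optional roles cover the variant ID, REF/ALT alleles, effect size (BETA or
OR), pre-computed r² and a gene symbol.  Two header columns resolving to
the same role is an error rather than a silent pick.  After reading:

* chromosome labels are stripped of any `chr` prefix and restricted to the
  canonical set 1–22, X, Y, MT (MT accepts `M`); rows on other contigs are
  dropped with a logged count — the Manhattan layout needs a fixed,
  total chromosome order;
* coordinates are 1-based inclusive throughout (matching Ensembl gene
  annotation conventions);
* p-values must lie in (0, 1]; exactly-zero p-values are clamped to the
  smallest positive double so `-log10` stays finite, and out-of-range or
  unparseable values drop the row (counted per reason);
* rows are sorted by (chromosome rank, position), a total order;
* when both BETA and OR columns are present, BETA is the effect source and
  OR is ignored with a warning, avoiding any risk of double conversion;
  OR-only datasets are converted with `β = ln OR` at the point of use;
* duplicate (chromosome, position) rows are retained at read time;
  multi-allelic duplicates are resolved downstream by the allele-matching
  step, which is the only place they are distinguishable.

The delimiter is auto-detected among tab, comma and whitespace unless
given, since summary-statistics dialects vary.

## Lead-variant selection

"Top variant per 1 Mb window" is implemented as greedy minimum-p selection
with a centred exclusion window, not fixed genome binning: fixed bins can
split one peak across a bin edge and report it twice.  Per chromosome,
candidates with `p < thresh` (default 5 × 10⁻⁸, strict) are visited in
(p, position) order; a candidate is accepted unless it lies within
`region_size / 2` bp (default window 1 Mb) of an already-accepted lead.
Conventions, chosen for determinism and testability: p-value ties break to
the smaller position; the exclusion boundary is strict, so a variant at
exactly `region_size / 2` bp is *not* excluded (accepted leads are
therefore ≥ half a window apart).  Greedy selection is monotone: tightening
the threshold never adds leads, shrinking the window never removes any.

## Nearest-gene annotation

Gene models carry a span, a biotype and merged exon intervals.  Queries use
an interval tree for overlap and sorted boundary arrays for the
non-overlapping case; tests compare against a naive exhaustive scan.
Rules: a position inside a gene returns that gene at distance 0; inside
several overlapping genes, the smallest span (most specific) wins, then the
alphabetically first symbol; otherwise the gene minimising the distance to
its nearer boundary wins, ties again alphabetical.  Distance is unstranded
base pairs to the nearer gene boundary, not to the TSS — "nearest gene" in
the plain positional sense.  The candidate set defaults to protein-coding
genes (real tracks are dominated by non-coding entries that would produce
unfamiliar labels) with a flag to include all biotypes.  A chromosome with
no candidates yields a sentinel value, not an exception, so bulk
annotation never aborts.  Tracks load from a small TSV dialect or from GTF
restricted to gene/exon features.

## Regions

A display region comes from exactly one of: a gene (span plus
`gene_padding`, default 100 kb each side, clipped at position 1), a variant
ID (position ± `variant_flank`, default 100 kb, mirroring the gene padding
since no other value is canonical), or literal coordinates
(`"chrom:start-end"`, tolerating a `chr` prefix and thousands separators).
Region width is `end − start`.

## Cross-cohort matching (snpset)

The pipeline composes four steps, each also exposed separately:

1. lead extraction from dataset 1 (above);
2. positional match: each lead is paired with *every* dataset-2 row at the
   same (chromosome, position); leads with no partner go to `not_found`;
3. allele reconciliation: identical REF/ALT pairs are kept unchanged;
   swapped pairs (REF₁ = ALT₂ and ALT₁ = REF₂) are kept after negating the
   dataset-2 effect and swapping its alleles (an involution — applying it
   twice is the identity); anything else goes to `no_allele_match`.
   Strand-ambiguous pairs (A/T, C/G) are handled by the literal swap rule
   only: reverse-complement matching is deliberately omitted because it
   silently mismatches ambiguous variants, and allele-frequency-based
   strand resolution is out of scope.  At multi-allelic positions at most
   one partner can reconcile; if duplicates reconcile, the first in
   position-sorted order is kept with a warning;
4. orientation: rows with a negative dataset-1 effect have both effects
   negated and both (now harmonised) allele pairs swapped, so E1 ≥ 0
   everywhere; E1 = 0 counts as non-negative.

The three outputs exactly partition the leads — an invariant the tests
assert over randomised cohorts.  `not_found` and `no_allele_match` keep the
original dataset-1 columns untouched for diagnostics.  The effect table
adds a gene label and a flag for dataset-2 genome-wide significance
(p₂ < 5 × 10⁻⁸), which the effect plot renders as filled-vs-unfilled
markers and black-vs-grey labels.

## Plot specification and rendering

Every plot function computes a declarative `PlotSpec` — panels of point
series, shades, reference lines, labels, rectangles and gene glyphs in
data coordinates — and the matplotlib renderer consumes only that.  The
split keeps layout logic pure and deterministic: golden tests compare
serialised specs, never pixels.  Numerical/layout choices that the display
conventions leave open, fixed here once:

* inter-chromosome gap: 0.3 % of the total genome span;
* chromosome span: the largest observed position (tracks the data rather
  than assuming a build);
* mirrored datasets (`ntop`) use `y = +log10 p ≤ 0`; axis tick labels show
  magnitudes;
* label collision: a greedy vertical repel separates labels closer than
  1 % of the x-range; user `nudge_x`/`nudge_y`/`angle` are applied on top
  and take precedence;
* r² bins for LD colouring: [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8),
  [0.8, 1.0] — the conventional locuszoom quintiles; a variant with r² = 1,
  when present, is drawn distinctly as the index variant;
* regional plots use three stacked panels (overview : main : genes at
  1 : 4 : 1 height); the overview's red region rectangle is widened to a
  minimum of 0.5 % of the chromosome span so very small regions remain
  visible as a line;
* the gene panel shows exon boxes when the region is narrower than 1 Mb,
  gene bodies otherwise (`show_exons` overrides); gene glyphs are packed
  greedily into rows such that no two glyphs in a row overlap, including
  an estimated label extent of 1.2 % of the region width per character;
* default colours come from a fixed qualitative palette indexed by dataset
  order; all per-dataset style options accept a scalar or a vector of
  length 1 or n.

## Synthetic data

The generator exists to exercise selection, annotation, matching and
layout logic with known ground truth, not to be population-genetically
realistic.  Background variants are uniform in position with
Uniform(0, 1) p-values (a pure null) and small Gaussian effects
(sd 0.02); a planted peak decays linearly in −log10 p from its apex
(default apex p = 10⁻¹²) over a configurable flank (default 200 kb,
25 variants), with effect magnitudes shrinking alongside and a consistent
sign — a deterministic stand-in for an LD block.  Alleles are sampled from
strand-unambiguous pairs unless ambiguous ones are requested.  The default
fixture genome is chromosomes 1–3 + X with lengths 10/8/6/5 Mb: large
enough for multi-chromosome layout and >1 Mb peak separation, small enough
for millisecond tests.  `paired_cohorts` derives a second cohort by
dropping a fraction of positions, corrupting alleles on a fraction,
swapping REF/ALT with negated effect on a fraction and adding Gaussian
effect noise, returning exact ground-truth labels; these predict the
snpset partition sizes by construction.

Because peaks are deterministic decays without LD structure, passing tests
show that the selection/matching/layout *logic* is correct under known
truth; they do not validate behaviour under real LD, population
stratification, or imperfect genomic control — those properties belong to
the upstream GWAS, not to this package.

## Problem sizes

The test suite and the acceptance script run on synthetic inputs of
120–5,000 variants, 200 randomised tables (≤ 1,000 rows) for the
lead-selection oracle comparison, 200 randomised tracks (≤ 25 genes,
5 queries each) for the nearest-gene oracle comparison, and 100 randomised
paired cohorts for partition conservation — sizes at which the brute-force
oracles are exact and fast while still covering multi-chromosome,
multi-peak and multi-allelic cases.

## Known limitations

* No VCF ingestion, tabix indexing, or liftover between genome builds;
  gene tracks are supplied as files rather than fetched from Ensembl.
* r² is consumed pre-computed; no LD calculation or LD-aware clumping.
* No meta-analysis; combined results are plotted as just another dataset.
* Rendering is static (PNG/SVG/PDF); no interactive output.
* The label repel is a simple greedy pass; very dense annotation may still
  need manual nudges.
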