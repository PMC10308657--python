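"""Regional association plot centred on a gene, with a gene/exon panel.

The region is the gene span plus 100 kb on each side (gene_padding).
Regions narrower than 1 Mb show exon structure on the gene panel.
"""

import gwasviz as gv

data = gv.simulate_sumstats(n_background=5000, peaks=gv.default_peaks(3), seed=1)
track = gv.simulate_gene_track(seed=1)

# pick the gene nearest the strongest peak
top = data.df.loc[data.df["P"].idxmin()]
gene = gv.nearest_gene(top["CHROM"], int(top["POS"]), track).gene

spec = gv.regionplot(data, gene=gene, track=track, annotate=1e-6)
gv.render(spec, "regionplot.png")

print(f"top variant {top['CHROM']}:{top['POS']} (p = {top['P']:.1e}), nearest gene {gene}")
print(f"displayed region: {spec.region_text}")  # copy into get_snps_within_region
shown = gv.get_snps_within_region(data, gv.resolve_region(region=spec.region_text))
print(f"{len(shown)} variants inside the displayed region")
genes_panel = spec.panel("genes")
print(f"gene panel: {len(genes_panel.genes)} gene(s), "
      f"exon structure = {any(g.show_exons for g in genes_panel.genes)}")
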