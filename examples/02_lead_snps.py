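"""Extract lead variants and annotate them with their nearest gene.

Lead (index) variants are the top variant per 1 Mb window with p below
5e-8; the window size and threshold control labelling density.
"""

import gwasviz as gv

data = gv.simulate_sumstats(n_background=5000, peaks=gv.default_peaks(4), seed=2)
track = gv.simulate_gene_track(seed=2)

leads = gv.get_lead_snps(data)  # thresh=5e-8, region_size=1 Mb
annotated = gv.annotate_with_nearest_gene(leads, track)
print(annotated[["CHROM", "POS", "P", "BETA", "Gene_Symbol"]].to_string(index=False))
print(f"\n{len(leads)} leads — one per planted peak; distance-0 rows sit inside a gene.")

# A sparser view of the same results: double the window, tighten the threshold
sparse = gv.get_lead_snps(data, thresh=1e-10, region_size=2_000_000)
print(f"with a 2 Mb window and p < 1e-10: {len(sparse)} leads")
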