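"""Two GWAS on one Manhattan plot: overlapping, then mirrored (ntop=1).

With ntop=1 the first dataset is drawn upward and the second downward on a
reversed y-axis — useful for visually comparing peak overlap between
cohorts of the same trait.
"""

import gwasviz as gv

cohort1 = gv.simulate_sumstats(n_background=4000, peaks=gv.default_peaks(3), seed=3)
cohort2, _ = gv.paired_cohorts(cohort1, drop_frac=0.05, effect_noise_sd=0.02, seed=4)

overlap = gv.manhattan([cohort1, cohort2], annotate=[1e-9, 1e-9],
                       track=gv.simulate_gene_track(seed=3))
gv.render(overlap, "multi_overlapping.png")

mirrored = gv.manhattan([cohort1, cohort2], ntop=1)
gv.render(mirrored, "multi_mirrored.png")

pts = mirrored.panel("main").points
print("orientations:", [(p.dataset, p.orientation) for p in pts])
print("legend:", [entry for entry in overlap.legend.entries])
print(f"bottom series max y = {max(pts[1].y):.2f} (mirrored values are <= 0)")
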