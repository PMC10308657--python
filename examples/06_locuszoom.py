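"""Regional plot coloured by linkage disequilibrium (r^2) bins.

r^2 of each variant against the index variant must be pre-computed with
external LD software and supplied as an R2 column; this example fakes a
plausible decay of r^2 with distance from the top variant.
"""

import numpy as np

import gwasviz as gv

data = gv.simulate_sumstats(n_background=3000, peaks=gv.default_peaks(1), seed=7)
track = gv.simulate_gene_track(seed=7)

df = data.df.copy()
top = df.loc[df["P"].idxmin()]
dist = np.abs(df["POS"] - top["POS"]) / 500_000.0
same_chrom = df["CHROM"] == top["CHROM"]
df["R2"] = np.where(same_chrom, np.exp(-dist), 0.0).round(3)
df.loc[top.name, "R2"] = 1.0  # the index variant itself
with_ld = gv.GwasDataset(df=df, label="regional+LD")

spec = gv.locuszoom(with_ld, region=f"{top['CHROM']}:{top['POS']-400000}-{top['POS']+400000}",
                    track=track)
gv.render(spec, "locuszoom.png")

for series in spec.panel("main").points:
    print(f"r2 bin {series.dataset}: {len(series.x)} variants")
# Bin colours follow the conventional locuszoom quintiles; the r^2 = 1
# variant is drawn as a distinct diamond.
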