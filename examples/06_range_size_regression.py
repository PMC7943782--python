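"""Phylogenetic regression of haplotype richness on range size.

Fits PGLS with Pagel's lambda: log haplotype count against log range size
and log specimen count, with Brownian-motion covariance from the species
tree scaled by lambda. AICc comparison asks whether range size contributes
beyond sampling effort.
"""

import numpy as np

from barcodelib import comparative as cp
from barcodelib import diversity as dv
from barcodelib.simulate import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(seed=42))
pc = cp.phylo_covariance(ds.tree())

tables = dv.species_tables(ds.library)
ranges = ds.ranges.set_index("species").loc[pc.species]
y = np.log([dv.chao1_asymptote(tables[s]) for s in pc.species])
x_range = np.log(ranges["range_size"].to_numpy())
x_spec = np.log(ranges["n_specimens"].to_numpy())

X = np.column_stack([np.ones_like(y), x_range, x_spec])
full = cp.pgls_fit(y, X, pc.V, response="log_estimated_richness",
                   predictors=["intercept", "log_range", "log_specimens"])
print(full.table().round(3).to_string())
print(f"lambda = {full.lambda_hat:.2f}, n = {full.n}, "
      f"R2 (whitened) = {full.r2_whitened:.2f}")
print("each coefficient: the partial effect on log estimated haplotype"
      " richness; lambda near 0 means residuals carry little phylogenetic"
      " signal here\n")

fits = {
    "range + specimens": full,
    "range only": cp.pgls_fit(y, X[:, :2], pc.V, response="log_estimated_richness"),
    "specimens only": cp.pgls_fit(y, X[:, [0, 2]], pc.V, response="log_estimated_richness"),
}
mc = cp.compare_models(fits)
print(mc.table.round(2).to_string(index=False))
print("delta AICc > 2 over both univariate models would show that range"
      " size and sampling effort each contribute independently")
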