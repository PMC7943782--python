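"""Latitudinal trend in haplotype richness via overlapping 0.5-degree belts.

Belt analysis: overlapping +-1 degree windows every 0.5 degrees; within each
belt, each species with >= 6 specimens is scored for sample-size-
standardized haplotype richness. An additive model (penalty-free regression
spline, k=10, plus mean conspecific distance) tests the trend; a loess
smoother (span 0.4) locates the richness peak.
"""

from barcodelib import spatial as sp
from barcodelib.simulate import SyntheticConfig, generate_dataset

# heavily sampled cohort; the configured richness gradient peaks at 42.5 N
ds = generate_dataset(SyntheticConfig(seed=42, specimens_coef=50.0))

tab = sp.belt_species_table(ds.library)
print(f"{len(tab)} qualifying (belt, species) pairs over "
      f"{tab['center'].nunique()} latitude belts")

trend = sp.fit_trend(tab)  # species random intercept, spline on latitude
print(f"smooth latitude term: Wald chi2 = {trend.smooth_stat:.1f} "
      f"on {trend.smooth_df} df, p = {trend.smooth_p:.2e}")
print(f"mean conspecific distance term: coef = {trend.distance_coef:.2e} "
      f"(p = {trend.distance_p:.2f})")
print("a significant smooth term means richness varies with latitude beyond"
      " what geographic spread of sampling explains\n")

means = sp.belt_summary(tab)
curve = sp.loess_curve(means["center"], means["richness_extrapolated"])
print(f"loess-smoothed belt richness peaks at {curve.argmax():.1f} degrees N "
      f"(configured gradient peak: {ds.config.lat_gradient.peak})")
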