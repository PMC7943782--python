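# barcodelib

Analyses for DNA-barcode reference libraries: haplotype diversity with
sampling completeness, probabilistic species identification, spatial
diversity trends, distance-based taxonomic audits, and phylogenetic
regression of genetic richness on range size.

## Who this is for

Builders and users of curated COI barcode libraries (BOLD-style: aligned
~658-bp sequences plus specimen metadata with a four-level taxonomy and
coordinates) who want to answer, reproducibly and from Python:

* How much of each species' haplotype diversity has the library captured?
* With what probability can a query barcode be assigned to its species,
  given that some species share barcodes?
* How does mitochondrial richness vary across latitude and longitude?
* Which taxa deserve attention because of deep intraspecific splits or
  near-zero distances to other species?
* Does range size predict haplotype richness once sampling effort and
  phylogeny are accounted for?

A seeded synthetic-library generator with known ground truth
(`barcodelib.simulate`) makes every stage testable without downloads.

## The models in brief

**Richness and completeness.** Per species, specimens collapse to
haplotypes with abundances x₁…x_S (n = Σxᵢ). Rarefied richness is the
hypergeometric expectation S(m) = Σᵢ [1 − C(n−xᵢ, m)/C(n, m)]; the
bias-corrected Chao1 asymptote Ŝ = S + ((n−1)/n)·f₁(f₁−1)/(2(f₂+1))
estimates total richness from singleton/doubleton counts; completeness is
S/Ŝ. Abundances are profiled over the log₂ octave classes 1, 2–3, …,
128–255.

**Identification.** A hierarchical classifier walks root → family →
subfamily → genus → species. Each node splits its probability among
children by a softmax on (d_min, d_avg) — the minimum and average
p-distance from the query to each child's references — with one weight
vector per level, trained by adaptive random-walk Metropolis
(N(0, 100²) priors, target acceptance 0.44, 1000 adaptation + 1000
sampling iterations, MAP from the sampling phase). Evaluation is
leave-one-out: a barcode never serves as its own reference.

**Spatial trends.** Overlapping ±1° belts every 0.5°; per belt, species
with ≥6 specimens are scored for sample-size-standardized richness.
Trends are fit as richness ~ spline(latitude, k=10) + mean conspecific
distance (species random intercept), and visualized by tricube local
quadratic loess (span 0.4).

**Comparative.** PGLS with Pagel's λ: log richness ~ log range +
log specimens with Brownian residual covariance from the species tree,
λ by profile ML, models compared by AICc (Δ > 2 separates).

## Worked example

`examples/04_probabilistic_identification.py` trains the classifier on a
synthetic 32-species library (20 specimens per species, one singleton
species, one introgressed species pair) and evaluates it leave-one-out:

```
$ python examples/04_probabilistic_identification.py
      family level: phase-2 acceptance 0.46
   subfamily level: phase-2 acceptance 0.43
       genus level: phase-2 acceptance 0.41
     species level: phase-2 acceptance 0.40
the adaptation phase tunes the proposal toward a 0.44 acceptance ratio

query -> Fam3_Sub2_Gen1_sp1 with probability 1.0000

leave-one-out over 621 specimens: specimen-weighted mean correct-species probability 99.34%
species below 99.9%:
  Fam2_Sub1_Gen1_sp1: 89.5%  (involved in barcode sharing)
  Fam2_Sub1_Gen1_sp2: 90.0%  (involved in barcode sharing)
singleton species score exactly 0: with their only barcode held out, no reference of that species remains
```

Reading the numbers: the four acceptance ratios show the MCMC proposal
settled near its 0.44 target; the query — a barcode of a well-separated
species — is assigned with essentially certainty; across the cohort the
mean probability of correct identification is 99.3%, and the only species
below the 99.9% plateau are the two linked by shared (introgressed)
barcodes, whose probability mass is split by the zero-distance references.

The other scripts in `examples/` each run one capability end to end:
library simulation and I/O (01), completeness and octave profiles (02),
distance audits and sharing cases (03), belt trends and the loess peak
(05), and the range-size regression with AICc comparison (06).

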