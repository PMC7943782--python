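# Methods

This note documents the statistical machinery in `barcodelib`, the
assumptions behind it, the synthetic data the test suite runs on, and the
numerical choices that matter when reproducing results.

## Reference libraries

A library couples aligned COI barcodes (FASTA) with a specimen table (TSV:
`specimen_id, family, subfamily, genus, species, latitude, longitude`).
Sequences are assumed pre-trimmed to a fixed frame (`L = 658` columns by
default) over the alphabet `{A,C,G,T,N,-}`; no aligner is included, and
ambiguity codes other than `N` are rejected. A record must carry at least
600 unambiguous positions to enter a library — `N`-padded fragments do not
qualify. An empty species field marks a genus-level identification; such
records are carried through I/O and excluded from species-level analyses.
Coordinates are decimal degrees (WGS84 semantics, no projection); a record
with an unparseable coordinate is kept, flagged, and skipped by the spatial
module.

## Haplotype diversity

Within a species, two barcodes share a haplotype iff they agree at every
position where both are unambiguous; grouping is the transitive closure of
this relation, so an `N`-rich sequence can merge otherwise distinct
haplotypes. This matches common barcode practice but is a genuine choice —
a `strict=True` mode (exact full-frame identity) is provided because the
right behaviour for `N`-heavy data is debatable.

Given the abundance vector `x_1..x_S` (n specimens, S observed haplotypes):

* rarefied richness `S(m) = sum_i [1 - C(n - x_i, m) / C(n, m)]` — the
  exact hypergeometric expectation of richness in an m-subsample;
* bias-corrected Chao1 asymptote
  `S_hat = S + ((n-1)/n) * f1(f1-1) / (2(f2+1))`, where `f1`, `f2` count
  singletons and doubletons (`S_hat = S` when `f1 = 0`); Chao1 is formally a
  lower bound on total richness and behaves as an estimate only when
  undetected haplotypes are rare-but-not-vanishing;
* extrapolation `S(n+m*) = S + f0_hat [1 - (1 - f1/(n f0_hat + f1))^{m*}]`
  with `f0_hat = S_hat - S`, which approaches `S_hat` as `m* -> inf`;
* sampling completeness `S / S_hat`; cohort summaries keep species with
  `n >= 6`, below which `f1/f2` carry almost no information.

Binomial coefficients are evaluated exactly (integer arithmetic) for
`n <= 1000` and via log-gamma beyond; the suite verifies the analytic
curve against exhaustive subset enumeration to 1e-9 for all abundance
vectors with `n <= 12`.

Octave profiles bin abundances into the eight log2 classes 1, 2–3, 4–7,
8–15, 16–31, 32–63, 64–127, 128–255; an abundance above 255 clamps into the
top class with a logged warning rather than growing a ninth class, keeping
the eight-class contract. Per-species relative frequencies are averaged
across species with their standard deviation (ddof = 1).

## Distances and audits

p-distance = differing sites / jointly unambiguous sites (pairwise
deletion, no model correction; indels never count). A pair needs at least
300 comparable sites (half the frame; configurable) to be valid. Outputs
print percentages to 2 decimals; internal values keep full precision, and
the matrix routine is contractually identical to the per-pair function.

Per species: mean and maximum intraspecific distance (undefined for
singletons) and the nearest-neighbour distance — the minimum over all
valid cross-species pairs, ties reported as a list. Audit flags (thresholds
in percent, strict inequalities): deep split when max intraspecific
p > 2.5; low divergence when 0 < nearest neighbour < 0.61 (the distance
four substitutions produce on the 658-site frame); shared when the nearest
neighbour is exactly 0. Barcode-sharing cases are the connected components
of the species graph with an edge wherever some valid cross-species pair
has p = 0; components are a partition, so a species belongs to at most one
case. The operational-vs-biological classification of a case is a
user-supplied annotation field, not inferred.

## Hierarchical probabilistic identification

The classifier walks a four-level taxonomy (root → family → subfamily →
genus → species). A query enters the root with probability 1; each node
splits its mass among candidate children by a multinomial (softmax)
regression whose per-child predictors are the minimum and the average
p-distance from the query to the child's reference sequences, plus an
intercept. The average distance makes the model frequency-aware: sharing a
rare haplotype costs a species less than sharing a common one. One weight
vector is shared by all nodes of a level (taxon-generic predictors keep
the parameterization identifiable at any taxonomy size), predictors are
standardized to zero mean/unit variance on the training set, and no
"unknown species" class exists — the taxonomy is closed. The shared
intercept cancels in the softmax; it is retained for the stated
three-parameter form and is pinned near zero by the prior.

Training records are built leave-one-out: every reference sequence, at
every node on its true path, scores all candidate children with itself
removed from its own reference sets. A child left with no references is
dropped for that record; when the dropped child is the true label (always
the case for singleton species) the record's log-likelihood is floored at
−30 with a reported count, so unreachable labels cannot dominate training.
The same convention at classification time is what makes a singleton
species' leave-one-out correct-assignment probability exactly zero.

Each level's posterior (likelihood + independent N(0, 100²) priors) is
sampled by random-walk Metropolis: 1000 adaptation iterations in which the
isotropic proposal scale follows the Robbins–Monro update
`s <- s * exp(gamma_t (alpha_t - 0.44))` toward a 0.44 acceptance ratio,
then 1000 iterations with the proposal frozen; classification uses the
maximum-posterior draw of the frozen phase (first-reached sample on ties).
The gain is `gamma_t = t^(-1/2)`: separable training sets flatten the
likelihood over a prior-scale plateau, and this schedule has enough total
adaptation capacity to traverse it within the adaptation phase while still
decaying to zero. Chains are single, per level, and fully determined by
the seed. Tree evaluation is exhaustive (no beam pruning), and at every
node the probabilities over included candidates sum to one; mass reaching
a node with no usable children is reported as unassignable.

## Spatial belts

Belt grids place centers every 0.5° (latitude 35–70 and longitude −9 to 36
by default); each belt gathers specimens within ±1° of its center (closed
boundary), so adjacent belts overlap. Within a belt, a species needs at
least six specimens to be scored. Two standardizations are computed:
(i) the rarefaction–extrapolation curve at the species' maximum belt
sample size across belts, and (ii) the analytic expected rarefied richness
at the species' minimum qualifying (>5) belt size. Method (ii) uses the
expectation rather than one random subsample — it is deterministic and
equals the mean of the draw-based procedure; at fixed m it converges to a
composition-only quantity as n grows, but carries the finite-population
correction at small n. Mean conspecific geographic distance per
(belt, species) is the all-pairs mean of haversine distances (R = 6371 km).
Belts with no qualifying species are dropped, so the realized belt count
can be below the nominal grid size.

`fit_trend` models richness as an additive function of the belt center
(penalty-free cubic regression spline, basis dimension k = 10, interior
knots at quantiles) plus the mean conspecific distance as a parametric
term; the smooth term's significance is a joint Wald test on its nine
coefficients. Two modes are exposed because the right observational unit
is genuinely open: the default fits per species-belt records with a
species random intercept (repeated species across belts are not
independent); the `belt-means` mode averages per belt and fits GLS with an
exponential (continuous-AR1) correlation on belt centers, range profiled
by maximum likelihood over a fixed grid — the random-intercept and the
spatial-correlation treatments are deliberately split across the modes
since the mixed-model machinery used here cannot carry both at once.
Overlapping belts reuse specimens, so residual dependence is understated
in the default mode; treat its p-values as screening statistics.

`loess_curve` is a tricube-weighted local polynomial smoother (quadratic
by default, span 0.4 of the data per window) evaluated on a uniform grid,
with a pointwise ±1.96·se band from the local smoother weights and a
global residual variance. With span 1 on polynomial data it reproduces the
global fit exactly. `spatial_subsample` thins to at most `cap` specimens
per `cell_deg` grid cell (seeded, deterministic), mimicking random
homogeneous subsampling; cell size and cap are configurable because no
canonical values exist.

## Phylogenetic regression

Brownian covariance from the species tree: `V[i,j]` = depth of the most
recent common ancestor of tips i and j. Pagel's lambda multiplies
off-diagonal entries only (`lambda` in [0,1]; no extension beyond 1 is
offered); `lambda = 0` makes GLS collapse to OLS exactly, which the suite
checks against statsmodels to 1e-8. `lambda` is estimated by profile
maximum likelihood on a 101-point grid followed by golden-section
refinement — slower than a gradient method but deterministic and immune
to local optima on the profile. Coefficient standard errors use the
unbiased variance estimate with n − k degrees of freedom and two-sided t
tests. R² is reported on the whitened scale (1 − RSS/TSS after the
lambda-hat transform) and, separately, on the raw scale, since conventions
differ. AICc = −2 logL + 2k + 2k(k+1)/(n−k−1) with k counting regression
coefficients plus the variance plus (when estimated) lambda; fits must
share n and response to be compared, and a difference above 2 separates
models. All richness/range/specimen variables enter log-transformed.

## Synthetic data: what it emulates and what it does not

The generator is the package's study system. Defaults (chosen once):

* taxonomy 4 families × 2 subfamilies × 2 genera × 2 species = 32 species;
  barcode frame L = 658;
* sequences mutate hierarchically from a random ancestral barcode (40 /
  20 / 12 substitutions at family / subfamily / genus rank); congeneric
  species carry ≥ 10 private substitutions each (disjoint sites, so sister
  species differ by ≥ 20 sites ≈ 3% — comfortably above the 0.61%
  near-dichotomy threshold); within-species haplotypes differ by one
  private site each; no indels, since p-distances ignore them;
* haplotype abundances follow a one-parameter geometric law with
  shape 0.9; the slow decay keeps singletons the modal octave class while
  leaving enough evenness for richness gradients to register in samples;
* range sizes are log-uniform on [1, 400]; specimen counts follow
  `round(3 * range^0.5 * lognormal(0, 0.4))` (widespread species sampled
  harder, with effort noise so range and effort are not collinear); true
  haplotype counts follow `exp(1 + 0.5 log range + N(0, 0.3))`, giving a
  recoverable log–log slope of 0.5;
* specimen coordinates are uniform over latitude 35–70 / longitude −9 to
  36; the number of haplotypes locally available at latitude ell is
  `round(K * g(ell))` with `g` a Gaussian bump peaked at 42.5° (width 4°)
  on a 0.2 floor — a southern-refugium-style richness gradient;
* optional: introgression pairs (n recipient specimens receive the donor's
  most common realized barcode, guaranteeing observable sharing) and
  forced singleton species. Defaults include neither.

Problem sizes used by the tests and the acceptance run: the
identification cohort fixes 20 specimens/species (~620 barcodes) with one
singleton and one congeneric introgressed pair; the spatial cohort raises
the effort coefficient to 50 (~5,000 barcodes) so most species clear the
six-specimen belt rule in most belts; the comparative cohort uses a
200-species taxonomy with responses simulated under Brownian motion
(range coefficient 0.125, sd 0.3).

Not emulated: demography and coalescence (haplotype trees have no
within-species genealogy), recombination, selection, endosymbiont sweeps,
sequencing error, missing data patterns (`N` runs, partial barcodes),
range-shaped (non-uniform) occurrences, and real taxonomic uncertainty.
Passing tests therefore demonstrate correctness of the estimators and
pipelines under the stated generative model — not that real libraries
satisfy that model. In particular real-data completeness, identification
and trend values depend on library size and structure and are not
reproduced here.

## Numerical conventions

Seeds: every stochastic routine takes an explicit seed or Generator;
per-level MCMC chains draw from `SeedSequence(seed).spawn`. Softmax and
GLS computations subtract maxima / use Cholesky whitening for stability;
degenerate scalers (sd < 1e-8) fall back to 1. Top-species ties break
lexicographically. `m_star = 0` extrapolation returns the observed
richness; `f1 = 0` makes the curve flat. Rank-deficient design matrices
raise instead of silently pseudo-inverting, except inside the loess local
solver where a pinv guards near-empty windows.
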