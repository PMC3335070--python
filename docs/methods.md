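# Methods

## The fourth-corner statistic

Given an aligned triple — **R** (sites × environmental variables), **L**
(sites × species counts), **Q** (species × traits) — each nonzero cell
(s, j) of **L** defines one occurrence row carrying the environment
vector of site s and the trait vector of species j, with weight
w<sub>sj</sub> = L<sub>sj</sub>/L<sub>++</sub>. The statistic for a
(trait, variable) pair is the weighted Pearson correlation over these
rows. The implementation never materializes the inflated table for the
full matrix: with W the weight matrix, a = W·1 the site masses and
b = Wᵀ·1 the species masses, all weighted means, variances and
cross-moments reduce to matrix products (Eᵀ W Q for the cross-moment
matrix), so one evaluation of the 26 × 16 study-scale matrix costs a few
microseconds. An explicit inflated-table path
(`inflate` / `fourth_corner_stat`) is kept as an independent route for
single cells and is cross-checked against the vectorized path and
against plain Pearson correlation on count-replicated occurrence tables.

Because weights are renormalized internally, raw counts and fractions of
total abundance give identical correlations; likewise the statistic is
invariant under affine rescaling of any environment or trait column.
Grand-total normalization (rather than per-site) is used for the
relative form; the two conventions cannot differ in r for the same
reason. Standardization uses the sample (n−1) standard deviation
throughout; any consistent choice cancels in r and leaves permutation
p-values unchanged.

## Permutation null models

Significance is assessed by reshuffling **L** and recomputing r:

* **model I** — each species' abundances are permuted across sites
  independently; null: no site–environment association *and* no
  species–trait association.
* **model II** — whole site rows of L are permuted (equivalent to
  reshuffling the rows of R); null: no site–environment association,
  species–trait link retained.
* **model IV** — whole species columns of L are permuted; null: no
  species–trait association, site–environment link retained.

Models III and V of the broader methodology are not implemented; the
analysis design this package supports uses I, II and IV only. Two-sided
p-values use the add-one convention p = (1 + hits)/(n_perm + 1), with
hits counted as |r\*| ≥ |r_obs| − 10⁻¹², so p ∈ (0, 1] always. The
default is 9999 permutations (a config parameter; the schematic-example
convention of 99999 is equally valid). Significance is reported per cell
at α = 0.05 with no multiple-testing correction by default; a Holm
adjustment is available (`holm_adjust`) but off by default, since the
model-comparison logic counts per-cell significances.

Permutations act on **L** alone, so a single permutation stream serves
every cell: p-values are independent of how many traits or variables are
analysed and of evaluation order. The stream is derived
deterministically from (seed, model label, retained-species subset), so
an analysis with a pairwise-deleted trait is bit-identical to the same
analysis run on the explicitly subset matrices.

### Calibration is conditional on the null

A permutation model is exact only in cells where its *entire* null
hypothesis holds. On communities with genuine species sorting (a real
L–R link), models I and II over-reject even for traits that are pure
noise: the permutations flatten the species' aggregation along the
gradient, making the null spread of r\* narrower than the sampling
spread of r_obs. Symmetrically, a real L–Q link inflates model I in
cells with noise variables. This is inherent to the method (it is why
sequential max-based combinations of models II and IV were later
proposed; those are out of scope here), not an implementation artifact.
The calibration suite therefore checks the 5% rejection rate on *fully
random* communities (both couplings zero), and the power suite checks
chance-level rejection only in cells coupled through neither side.
Interpretation guidance: compare counts *between* models rather than
reading model-I cell counts as exact false-positive rates.

## Missing trait values

Traits are not measured for every species. For each trait, species
lacking that trait are dropped together with their L columns for that
trait's test only (pairwise deletion), and the weights renormalized.
Trait columns sharing a missingness pattern are processed together.
Cells whose correlation is undefined after deletion (zero weighted
variance) are reported as NaN and excluded from significance counts
rather than counted as zeros.

## Intraspecific pipeline

Replicate trait values (long table: species, plot of sampling, trait,
value) are z-normalized within each (species, trait) group using the
sample standard deviation; groups need ≥ 2 values and nonzero spread.
Species with fewer than two measured individuals are dropped, as are
traits that vary within no species. Normalization removes all
interspecific signal: adding a constant to one species' raw values
changes nothing downstream. Per plot and trait, the normalized values of
the species measured in that plot are averaged with weights equal to the
species' abundances in that plot (replicates of a species within one
plot are averaged first). Each trait's plot scores are regressed (OLS,
two-sided slope test) on each environmental variable; pairs with fewer
than three usable plots are skipped and logged but remain in the
n_tests = (#retained traits) × (#variables) grid, against which the
chance expectation α · n_tests is reported.

## Rarefaction and structure variables

Hurlbert's rarefied richness E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)] is
evaluated in log-gamma space, so censuses of any size are safe from
overflow; species with N−Nᵢ < n contribute exactly 1. The default
subsample is 100 individuals. When a site holds fewer than n individuals
the observed richness is returned with a warning — the choice is ours;
alternatives (NaN, refusing) would propagate awkwardly into the site
table. Structure variables per site: total individuals, observed
richness, rarefied richness, and the proportion of individuals belonging
to deciduous species (a 0/1-coded trait names the deciduous indicator;
species-level coding is assumed, i.e. all individuals of a species share
its phenology).

## Ordination

PCA of standardized matrices (correlation structure) via singular value
decomposition. Loadings are orthonormal; axes are ordered by explained
variance; each axis is oriented so its largest-magnitude loading is
positive, making outputs deterministic. At full rank,
scores · loadingsᵀ reconstructs the standardized input.

## Synthetic communities

The generator emulates gradient-driven environmental filtering: sites
sit at equally spaced positions g ∈ [0, 1]; species optima μ_j are
uniform on the gradient; expected abundance is Gaussian,
λ_sj = A·exp(−(g_s−μ_j)²/2σ²), with Poisson counts (negative-binomial
overdispersion behind a flag). Environmental variable k is
γ_k·g_s + N(0, σ_E); trait m of species j is β_m·μ_j + N(0, σ_T). A
(trait, variable) pair is truly coupled iff β_m ≠ 0 and γ_k ≠ 0, and the
ground truth (gradient, optima, slopes, coupled pairs) is stored with
every dataset.

Defaults mirror a 27-plot subtropical-forest succession survey: 27
sites, 122 species, 16 variables, 26 traits, with the first half of the
variables gradient-coupled (slope 1) and the first half of the traits
optimum-coupled (slope 2); σ = 0.15 gradient units, A = 15 expected
individuals at the optimum (site totals of a few hundred individuals),
noise standard deviations 0.3, intraspecific sd 0.25. Replicate tables
sample each species in up to k (default 5) of its occupied plots, one
individual per plot — species occupying a single plot end up dropped by
the ≥ 2-individuals rule, as in real surveys of rare species. An
optional env_slope adds an environment-dependent within-species shift
for power studies; zero slope gives the intraspecific null.

What the generator does *not* emulate: multiple interacting gradients
(a second orthogonal gradient is configurable but off by default),
spatial autocorrelation and dispersal limitation, phylogenetic trait
structure, detection error, and trait–trait covariance beyond shared
dependence on the optimum. Passing tests therefore demonstrate
correctness and calibration of the estimators under idealized filtering,
not robustness to those real-data complications.

## Problem sizes and numerics

The test suite runs study-scale dimensions (27 × 122 × 16 × 26) for
power checks with 199–999 permutations and 20–100 replicate datasets,
and 500 small (10 × 20 × 3 × 4) communities with 199 permutations for
null calibration; these sizes give binomial Monte-Carlo error well
inside the 99% envelopes used. Envelope checks treat datasets — not
cells — as the independent units, which is conservative when cells
within a dataset are positively correlated through the shared
permutation stream. Weighted variances below a 10⁻¹³ relative threshold
are treated as zero (undefined correlation); r is clipped to [−1, 1]
against rounding; exact-equality determinism is guaranteed only for
identical seed, inputs and library versions.

## Known limitations

* Environmental variables and traits must be quantitative or 0/1;
  multi-level factors are not supported.
* No spatial or phylogenetic corrections; no RLQ-style joint ordination;
  no sequential model combination.
* Model-I p-values in the presence of a real single link are
  anticonservative by construction (see above); use the model
  comparison, not raw model-I counts, for inference about mechanism.
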