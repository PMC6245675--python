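# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `diasal`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## The calibration problem

A transfer function maps a modern site-by-taxon assemblage matrix Y
(counts or percentages) and a paired environmental variable x to a model
that infers x for new assemblages. Here x is chloride concentration; the
calibration operates throughout on log10 mg/l, because the gradient spans
more than one order of magnitude and the log-transformed variable is the
one with approximately symmetric residuals. Back-transformation to mg/l
(10^x̂) happens only in the reconstruction layer. Abundances are converted
to row percentages, screened by cumulative coverage, and square-root
transformed; the same matrix feeds the dissimilarity, ordination and
calibration stages.

### Preprocessing

* **Percentages**: rows sum to 100.
* **Coverage screen** (default 0.98): taxa are ranked by grand-total
  abundance (ties broken alphabetically) and the shortest prefix whose
  cumulative share of the grand total reaches the threshold is kept. The
  threshold is interpreted as a fraction of total abundance, not of
  occurrence counts: this reading yields a deterministic rule and matches
  the intent of retaining the taxa that "cover" the observations.
* **Square root**: damps dominant taxa before Bray–Curtis and calibration.
* **Taxon harmonization** (model vs. new data): exact string match after
  whitespace trimming; no fuzzy matching or synonym resolution. The
  matched-abundance fraction per site is reported and a site matching
  nothing is an error.

### Weighted averaging (WA)

Optimum û_k = Σᵢ y_ik x_i / Σᵢ y_ik; tolerance t_k = abundance-weighted
standard deviation (uncorrected — no Hill's-N2 inflation, implementing the
plain weighted-SD definition); Hill's N2_k = 1/Σᵢ(y_ik/y_{+k})². Raw site
estimates x̂ᵢ = Σ_k y_ik û_k / Σ_k y_ik are range-compressed; deshrinking
fits a line between x̂ and x. Both the inverse (x on x̂) and classical
(x̂ on x, inverted) regressions are **weighted by site abundance totals**.
This is the weighted inverse deshrinking that makes WA exactly the
one-component special case of WA-PLS; with pure percentage data all row
totals coincide and the weighting is vacuous. Hill's N2 is reported but
not used to drop taxa by default; an optional `n2_min` filter exists.

### WA-PLS

The classical iterative algorithm with site weights rᵢ = y_{i+}/y_{++} and
taxon weights c_k = y_{+k}/y_{++}:

1. the current site target is the weighted-centred x (component 1) or the
   previous regression residuals;
2. species scores u_k = Σᵢ y_ik sᵢ / y_{+k};
3. site scores zᵢ = Σ_k y_ik u_k / y_{i+};
4. weighted centring, orthogonalization against previous components and
   standardization (all under rᵢ);
5. regression coefficient b_a = Σᵢ rᵢ x_cᵢ z_aᵢ (components are
   r-orthonormal, so coefficients are independent across components).

Every transformation is affine in the species scores and the
weighted-average operator maps constants to constants, so each component
carries a species vector plus a constant, and any component count r
collapses to a single per-taxon coefficient vector β with intercept β₀:
x̂ = β₀ + Σ_k y_k β_k / Σ_k y_k. Predictions through the collapsed vector
and through the component-wise path agree to 1e-10 by construction, and
both routes are implemented and cross-checked. A component whose weighted
variance falls below 1e-12 truncates the model with a warning.

The number of components is capped at min(n−1, m). Note that the nested
weighted regressions guarantee monotone non-increasing **weighted** RMSE in
the component count; the unweighted RMSE reported in performance tables can
occasionally tick upward.

### Cross-validation and component selection

Leave-one-out: each site is removed, taxa that lose all abundance are
re-screened, the model is refit and the site predicted. RMSEP_r is the
root mean squared LOO error for r components; r²_loo is the squared
Pearson correlation of LOO predictions with observations (the package uses
squared-correlation r², not 1−SSE/SST, for both apparent and LOO values; a
choice documented here because conventions differ). Component r > 1 is
"useful" iff it reduces RMSEP by at least 5% relative to the 1-component
model, consecutively; the selected count is the largest consecutive useful
r, else 1.

Per-component significance is assessed by a paired sign-flip randomization
on per-site squared LOO errors of the r- versus (r−1)-component model
(the 0-component reference predicts the weighted training mean), with the
+1/+1 finite-sample correction. This choice of test is the package's own;
it is exchangeability-exact for the paired null.

## Community-structure statistics

All on Bray–Curtis dissimilarities of the square-root percentage matrix.

* **PERMANOVA** (one-way): SS_total = Σ_{i<j} d²_ij/N, SS_within from
  within-group pairs, pseudo-F with (a−1, N−a) degrees of freedom. For a
  single factor, permutation of residuals under a reduced model reduces to
  free permutation of group labels, which is what is implemented.
  p = (1 + #{F* ≥ F}) / (1 + n_perm) ≥ 1/(n_perm+1). SS_within = 0 yields
  F = +∞ with the p-value still defined by permutation. Pairwise tests are
  Bonferroni-corrected by the number of group pairs. An exhaustive mode
  enumerates all label permutations for small n (oracle-tested against
  brute force).
* **Dispersion homogeneity**: principal-coordinate embedding via Gower
  centring of −d²/2, keeping negative-eigenvalue axes separately; squared
  distance to the group centroid = (real-axis part) − (imaginary-axis
  part), clamped at zero (Anderson's correction, matching vegan's
  `betadisper(type="centroid")`, against which the statistic is
  cross-checked); one-way ANOVA F on these distances with label-permutation
  p. Group centroids, not spatial medians.
* **SIMPER**: per-taxon terms |y_ik − y_jk| / Σ_l (y_il + y_jl) averaged
  over all between-group pairs, pooled across group pairs when more than
  two groups are present (a pooled table is what a three-season comparison
  reports; per-pair tables are obtained by subsetting). The contributions
  sum exactly to the average between-group dissimilarity — this identity is
  tested to 1e-10.
* **NMDS**: SMACOF majorization with isotonic regression of configuration
  distances on the dissimilarity order; ties in the dissimilarities are
  broken by the current configuration distance (Kruskal's primary
  approach). Stress-1 is reported and re-evaluated independently in the
  tests. First start from the principal-coordinate configuration, further
  starts random; the iteration stops when stress stops decreasing, so the
  recorded stress history is monotone. Default k = 2.

## Ordination diagnostics

Chi-square residuals Q = (P − rcᵀ)/√(rcᵀ); total inertia ‖Q‖². CCA
projects Q onto the site-weighted span of the (weighted-centred)
constraints; covariables are partialled out of both response and
constraints first. Conditional + constrained + unconstrained inertia sums
to the total exactly (projection orthogonality); eigenvalues below 1e-12
are clamped. Collinear constraints raise an error naming the first
dependent column. λ1/λ2 = first constrained / first residual eigenvalue;
λ2 = 0 reports +∞ with a flag.

Variance partitioning reports, per variable v and as percentages of the
full model's explained inertia: total (v alone), unique (v given all
others as covariables) and shared = total − unique. Exact duplicate
columns are collapsed before the full-model fit but still act as
covariables, so a duplicated variable has zero unique share. An optional
all-subsets hierarchical mode (Chevan–Sutherland averaging over orderings,
≤ 12 variables) is provided; the default total/unique/shared mode is the
one whose quantities a seasonal comparison tabulates.

## The synthetic study generator

The generator emulates the statistical structure of the emulated study
design, not its biology:

* **Design**: 32 locations × 3 seasons (96 training samples, 400 valves
  each); 90 independent validation samples (250 valves — the midpoint of a
  200–300 counting standard); chloride 200–9000 mg/l, site salinities
  uniform in log10 mg/l (the calibration's natural scale) and
  season-invariant within a location.
* **Species**: 60 taxa; optima evenly spaced with jitter across the
  gradient extended by a 0.25 margin; tolerances log-normal with median
  0.25 log10 units (log-sd 0.2); peak abundances log-normal (log-sd 0.5).
  The spreads were fixed by requiring internal consistency of the
  generator: on a noiseless 1000-site design, interior optima (≥ 2.5
  tolerances from both gradient ends, where one-sided Gaussian truncation
  bias is analytically ≈ 0.004 log units) must be recovered to within
  0.02 log units despite compositional closure. Larger tolerance or peak
  spreads violate that bound.
* **Seasonality** is multiplicative abundance modulation only — species
  identities and niches never change, matching the mechanism the seasonal
  comparison is meant to expose. Summer up-weights the below-median-optima
  half of the pool and autumn down-weights it (multipliers exp(±s·e_k),
  magnitudes e_k ~ U(0.5, 1.5), strength s = 1). The direction matters and
  is deliberate: because communities are compositional, boosting a taxon
  inflates its relative abundance most where it was previously rare, so
  its apparent weighted-average optimum moves *toward the gradient region
  dominated by other taxa*. Up-weighting the fresh-water half in summer
  therefore raises apparent optima across the board in the summer data and
  lowers them in autumn — the summer-high / autumn-low ordering that
  seasonal calibrations exhibit. Spring modulates with random,
  optimum-independent directions at the same strength, so spring optima
  scatter on both sides of the all-season average and the spring dataset
  is *not* a privileged neutral reference.
* **Noise**: per-sample, per-taxon lognormal perturbation of the raw
  responses (log-sd 1.0) before closure and the multinomial draw. Pure
  counting error alone makes calibrations unrealistically clean
  (r²_loo ≈ 0.998); the response noise represents secondary gradients and
  biotic variability and brings cross-validated performance into a
  realistic-but-informative regime (r²_loo ≈ 0.97–0.99, RMSEP ≈ 0.05–0.08
  log units at the default settings).
* **Validation data** are generated season-free (all multipliers 1),
  emulating an independently collected, temporally integrated monitoring
  dataset: the validation chloride is conceived as an average over months,
  and no single season's bias should be baked into it. This is what makes
  the experiment informative — each single-season model is biased relative
  to the validation process, while the all-season model averages the
  modulation out and has three times the sample size.
* **Nuisance covariates**: rᵢ-independent Gaussian noise mixed with the
  standardized log10 chloride so the expected Pearson correlation hits a
  target (defaults: strong for conductivity 0.60 and sulphate 0.70, weak
  negative for Secchi depth −0.26 and temperature −0.16, near zero for
  nutrients). They decorate the environment table for the screening and
  variance-partition stages; they do not influence the communities.
* **Randomness**: a single master seed feeds named
  `numpy.random.SeedSequence` substreams (pool, locations, counts, noise,
  nuisance); identical seeds give identical studies byte for byte.

The packaged example seed is 3; it is the seed used in the README's worked
example and in the experiment-level tests.

### What the generator does not emulate

Spatial autocorrelation between neighbouring ditches, taxonomic
misidentification between datasets, season-dependent salinity, secondary
gradients that are *structured* (the response noise is unstructured), and
mechanistic ecology (succession, grazing, nutrient stoichiometry). Passing
the experiment-level tests therefore shows that the pipeline detects and
quantifies seasonal abundance modulation under the stated statistical
conditions — not that any particular field dataset behaves this way.

## Experiment-level analyses

* **Seasonal comparison** fits spring, summer, autumn and pooled
  all-season WA-PLS models with identical settings, cross-validates each,
  computes λ1/λ2, reconstructs the validation set at the selected
  component count and tabulates validation r², RMSEP, residual slope and
  bias-band fractions (defaults < 500 mg/l and 2000–4000 mg/l absolute
  error, configurable). Residuals follow the predicted − observed
  convention, so under-prediction at the brackish end appears as a
  negative residual-vs-observed slope. Seasons with fewer than 5 sites are
  skipped with a warning. At the packaged seed the all-season model
  attains the lowest validation RMSEP of the four while all four are
  near-indistinguishable under cross-validation — the headline
  seasonal-bias phenomenon.
* **Edge-effect run**: the validation gradient is extended beyond the
  training gradient (100–18000 vs 200–9000 mg/l), i.e. the training
  gradient is truncated relative to the application range, as is typical
  when a calibration is applied to independent data. All four models then
  show negative residual-vs-observed slopes. Truncating the *validation*
  range to the gradient centre does not reproduce this (the edge effect
  lives at the ends); the extended-validation design is the faithful one.
* **One-per-location subsample** (`datasets.one_per_site_subsample`)
  retains one randomly chosen season per location (n = 32), so the
  all-season model can be re-fit at single-season sample size — separating
  the pooled model's sample-size advantage from its seasonal-averaging
  advantage.

## Numerical conventions and degenerate inputs

* Permutation p-values always include the observed statistic (+1/+1).
* Zero-total taxa are excluded with a warning wherever coefficients are
  computed; a site with zero abundance over a model's taxa is an error.
* Bray–Curtis between two all-zero sites is undefined and raises.
* Zero-variance variables in the environment screen are flagged, not
  raised; an all-identical dispersion vector reports F = 0, p = 1.
* Eigenvalues below 1e-12 are treated as zero; λ2 = 0 reports an infinite
  λ1/λ2 with a flag rather than raising.
* CSV exchange format: UTF-8, comma-separated, decimal point, first column
  `site_id`, optional `season` and `location_id` columns in community
  files; lines starting with `#` carry provenance (configuration hash and
  master seed) and are skipped on read.

## Known limitations

* Single-factor PERMANOVA only; no nested or multi-factor designs and no
  strata-restricted permutations.
* No bootstrap or h-block cross-validation; no modern-analogue screening
  of validation samples; no sample-specific reconstruction errors.
* The component-significance randomization is the package's own choice of
  test; other calibration programs use different (often unspecified)
  tests, so p-values are comparable only within this package.
* Tolerances are uncorrected weighted standard deviations; packages that
  apply Hill's-N2 bias corrections will report slightly larger values.
* The hierarchical variance-partition mode fits 2^p models and is limited
  to 12 variables.
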