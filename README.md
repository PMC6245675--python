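# diasal

Diatom-based salinity transfer functions, with the statistics needed to ask
an uncomfortable question: *does the season you sampled in change what your
calibration believes about species niches — and how badly does that hurt an
independent reconstruction?*

`diasal` is aimed at palaeolimnologists and aquatic ecologists who build
weighted-averaging calibrations from modern surface samples and apply them
to fossil or independently collected assemblages. It implements the full
inference pipeline around a seasonal brackish-water study design — 32
locations sampled in spring, summer and autumn along a 200–9000 mg/l
chloride gradient, validated against an independent 90-sample monitoring
dataset — together with a synthetic community generator that emulates that
design, so every step can be exercised and stress-tested without the
original field data.

## What is inside

* **Weighted averaging and WA-PLS calibration.** A taxon's *optimum* is its
  abundance-weighted mean of the environmental variable,
  û_k = Σᵢ y_ik x_i / Σᵢ y_ik, its *tolerance* the abundance-weighted
  standard deviation, and Hill's N2 its effective number of occurrences.
  WA infers a site value as the abundance-weighted mean of the optima of
  the taxa present and corrects the resulting range compression by a
  (site-total-weighted) inverse or classical deshrinking regression.
  WA-PLS extends this with further components extracted from the residual
  structure; the one-component model is exactly WA with weighted inverse
  deshrinking. Leave-one-out cross-validation yields r² and RMSEP per
  component count; the component count is chosen by the "5% RMSEP
  reduction over the 1-component model" rule, with a sign-flip
  randomization test on paired LOO errors as a significance check.
* **Community structure.** Bray–Curtis dissimilarities on square-root
  transformed percentages; one-way PERMANOVA (9999 permutations, pairwise
  tests with Bonferroni correction); the multivariate-dispersion
  (distance-to-centroid) homogeneity test with negative-eigenvalue
  correction; SIMPER decomposition of between-group dissimilarity into
  per-taxon contributions; NMDS (Kruskal stress-1, SMACOF with isotonic
  regression, principal-coordinate start plus random restarts).
* **Gradient diagnostics.** (Partial) canonical correspondence analysis;
  the λ1/λ2 ratio (first constrained over first residual eigenvalue — a
  value above 1 marks a variable as a useful calibration target); variance
  partitioning of explained inertia into per-variable total, unique and
  shared components.
* **Independent validation.** Taxon harmonization between model and new
  data, back-transformation to mg/l, observed-vs-inferred statistics,
  residual-versus-observed regression (the edge-effect signature) and
  bias-band fractions in concentration units.
* **Synthetic study generator.** Gaussian (unimodal) species responses on
  log10 chloride, multiplicative seasonal abundance modulation,
  per-sample lognormal response noise, multinomial valve counts (400 per
  training sample, 250 per validation sample) and nuisance covariates with
  prescribed correlations to salinity. Ground truth is retained so optima
  recovery can be measured.

## Worked example: the seasonal-bias experiment

```python
import warnings
from diasal.simulate import SimulationConfig, simulate_study
from diasal.reconstruction import compare_seasonal_models

study = simulate_study(SimulationConfig(), seed=3)
res = compare_seasonal_models(
    study.training_community, study.training_environment,
    study.validation_community, study.validation_environment,
    max_components=3)
cols = ["n_sites", "n_components", "r2_loo", "rmsep_loo",
        "lambda_ratio", "validation_rmsep", "residual_slope"]
print(res.table[cols].round(3).to_string())
```

prints

```text
        n_sites  n_components  r2_loo  rmsep_loo  lambda_ratio  validation_rmsep  residual_slope
model
spring       32             3   0.982      0.061         2.210             0.082          -0.108
summer       32             3   0.986      0.056         2.088             0.128          -0.020
autumn       32             3   0.990      0.046         1.895             0.115          -0.017
all          96             3   0.974      0.074         2.119             0.068          -0.052
```

How to read it: by leave-one-out cross-validation every
model looks excellent (`r2_loo` ≈ 0.98, RMSEP ≈ 0.05–0.07 log10 units) and
every model sees salinity as the dominant gradient (λ1/λ2 ≈ 2 > 1). The
independent validation tells a different story: the single-season summer
and autumn models predict the season-free validation assemblages much
worse (`validation_rmsep` 0.128 / 0.115) than the pooled all-season model
(0.068), because their optima are shifted by the seasonal abundance
modulation. The negative `residual_slope` values are the classic edge
effect of averaging-based calibrations — over-prediction at the fresh end,
under-prediction at the brackish end.

The same workflow is available from the shell:

```sh
diasal simulate --config run.yaml          # writes the synthetic study CSVs
diasal analyze  --config run.yaml --plots  # full pipeline + figures
diasal calibrate --config run.yaml         # fit + export one model as JSON
diasal reconstruct --config run.yaml --model results/model.json
diasal compare  --config run.yaml          # seasonal comparison table only
```

with a YAML configuration holding one master seed, the file paths and the
analysis options (see `diasal.config`).

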