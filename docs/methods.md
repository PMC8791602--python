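# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Concentration models

For a fish sample *i* of species *sp* in family *f* at site *s*:

* gamma likelihood in mean/shape form, `y ~ Gamma(mu, k)` with
  `E[y] = mu`, `Var[y] = mu^2 / k`, log link:
  `log mu_i = alpha + a_f + a_s + beta' x_i (+ b6_sp HAB_i)`.
* calcium instead uses `log y ~ Normal(eta, sigma)`; predictions are
  back-transformed by exponentiating draws (median-unbiased; no
  lognormal mean correction is applied, and none is claimed).
* covariates `x = (K, TL, AM, PEL, LMX)` are centered and scaled by the
  mean/SD over the **species** represented in the fit (one row per
  species, not per sample), so the scaling is insensitive to unequal
  sampling across species. An `scaling="unscaled"` refit supports
  out-of-range prediction for unsampled species; the suite checks the two
  fits agree within 2 % on in-sample predictions.

Intercept structures:

* `family_site` (default): family and site intercepts.
* `species_site`: iid species intercepts (used by the habitat model).
* `phylo_species_site`: species intercepts `a = L(eta2, rho) z` with
  `S = eta2 * exp(-rho * d) + 1e-6 I` (Ornstein–Uhlenbeck kernel on the
  normalized phylogenetic distance matrix, non-centered via the Cholesky
  factor).

Hierarchical effect blocks enter the linear predictor **sum-to-zero
centered** (`sigma * (z - mean z)`, or `a - mean a` for the phylogenetic
block). This removes the exact ridge between the global intercept and
each block mean — a reparameterization, chosen because it leaves trait
coefficients, predictions, and variance components essentially unchanged
while making the posterior well-conditioned for gradient-based sampling.
Reported family/species effects are the centered (identified) ones.

Priors (defaults; a YAML `PriorTable` can override any of them, e.g. to
supply informative trait-coefficient priors from a global marine-fish
analysis — using the weak defaults triggers a warning):

| parameter | prior |
|---|---|
| trait coefficients | Normal(0, 1), provenance `weak_default` |
| average habitat effect `b6` | Normal(0, 1) |
| global intercept | Normal(0, 10) |
| family/site/species/slope SDs | Exponential(1) |
| gamma shape `k` | Exponential(0.05) |
| lognormal sigma | Exponential(1) |
| OU `eta2`, `rho` | Exponential(1), Exponential(0.5) |

The habitat model is fitted to the species observed in **both** habitat
regimes (it subsets its input automatically). With per-species intercepts
plus five trait covariates over ten species, the trait block is collinear
with the intercepts and identified only through shrinkage; this is
faithful to the varying-slopes design and is why that model defaults to
longer HMC trajectories (below).

## Sampling

Everything is sampled with plain HMC using exact analytic gradients
(including the Cholesky forward-mode rule for the OU kernel parameters).
Defaults: 3 chains × 1,200 kept draws after 600 warmup iterations;
leapfrog length jittered in [8, 32] ([32, 64] for the habitat model and
other strongly correlated posteriors); dual-averaging step size targeting
0.8 acceptance; diagonal mass matrix initialized from the L-BFGS
inverse-Hessian at the MAP and re-estimated from the middle half of
warmup. Convergence is enforced at rank-normalized split-R-hat ≤ 1.01 on
the key parameters (trait coefficients, intercept, habitat effect);
fitting raises `ConvergenceError` with the full diagnostics payload
otherwise. Proposals with Hamiltonian error > 1000 count as divergences.

Sampler calibration is tested two ways: recovery of known Gaussian
targets, and simulation-based calibration on the trait model (200
replicates of prior draw → data → posterior; rank statistics of the true
intercept and trophic-level coefficient tested for uniformity by χ² at
α = 0.01, with thinned draws to control autocorrelation).

## WAIC

`waic = -2 (lppd - p_waic)` with `lppd_i = log mean_d exp(ll_di)` and
`p_waic_i = var_d(ll_di)` using the **sample** variance over draws
(n−1 denominator, as in the comparative-methods literature). The suite
pins this to a literal two-loop reference at 1e-10 and to arviz after
converting its population-variance convention. Model selection between
family and phylogenetic intercepts records both WAICs but keeps the
simpler family model for prediction by default (a `strict` flag follows
the WAIC winner instead); linear-vs-quadratic PC1 regressions are always
chosen by lower WAIC.

## Quality control

Below-LOQ samples are removed first. Then, per nutrient, values greater
than `mean + 2 × SD` (one-sided, single pass, no iteration) are removed,
with mean/SD computed on the post-LOQ set. The "two standard errors"
wording of the originating protocol conflicts with its reported 3–5 %
removal rate (SEM at n ≈ 180 would remove far more), so SD is the
default spread and SEM is available via `spread="sem"`.

## Synthetic-data generator

The generator is the package's study design, with every parameter in
`SyntheticConfig` and the realized values in `GroundTruth`:

* **Scale**: 44 species in 11 families; 12 sites; surveys in 1994, 2005,
  2008, 2011, 2014, 2017 around a 1998 disturbance; 8 replicate 154 m²
  point counts per site-year; 4 fish per species plus 7 macroalgal fish
  for each of 10 dual-habitat species (→ ~110 habitat-model samples,
  matching the study scale); every fish measured for all five nutrients.
* **Traits**: log-normal K, AM, LMX; normal TL clipped to [2, 4.5];
  Bernoulli PEL (p = 0.3). LMX and PEL are thresholded from a latent
  bivariate normal with correlation 0.85, which yields a point-biserial
  r ≈ 0.66 (the moderate 0.55–0.75 band). Distances come from a latent
  3-D embedding (family centres + jitter), so the exponential kernel on
  them is automatically positive definite.
* **Concentrations**: intercepts give field-realistic medians (Ca 40 mg,
  Fe 1 mg, Se 40 µg, Zn 1.15 mg, n-3 0.3 g per 100 g); trait effects are
  modest (selenium/omega-3 rise with trophic level, iron/zinc fall); the
  habitat effect is ln 1.5 for iron and ln 1.2 for zinc, zero elsewhere;
  gamma shape k = 10 per nutrient (within-species residual spread is not
  reported anywhere authoritative, so this is an explicit, configurable
  choice); species habitat slopes jitter around the average with SD 0.05.
  Small fractions of below-LOQ flags (1 %) and ×8 contamination outliers
  (2 %) exercise the QC filter.
* **Surveys**: Dirichlet-multinomial species composition per point count;
  on shifted reefs post-disturbance, herbivore weights double; total
  abundance grows linearly to ×3 by the final year so that availability
  rises after bleaching. Benthic trajectories: high coral everywhere
  pre-disturbance; shifted sites hold 33–75 % macroalgae afterwards while
  recovery sites stay below 10 % and regain coral — the two bands never
  overlap, by construction. Length–weight conversion uses a = 0.01,
  b = 3 unless a species table is supplied. ~40 % of sites
  (`regime_split = 0.4`) take the macroalgal trajectory,
  deterministically the first sites in index order.
* **Seeds**: one master seed; each stage (traits, phylogeny, nutrients,
  surveys, benthic, contamination) uses a fixed-offset sub-seed recorded
  in `GroundTruth.seeds`. Everything is bit-reproducible.

What the generator does **not** emulate: real species lists or
phylogenies, observed nutrient values, spatial structure beyond site
labels, observer/detectability error, or species-specific length–weight
coefficients. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the assumed generative model — not
agreement with any field dataset.

## Downstream conventions

* Biomass: masses summed within a point count, averaged over replicates
  (absences contribute zero), divided by 154 m² and converted at
  1 g m⁻² = 10 kg ha⁻¹. The replicate count defaults to the distinct
  point-count ids present per site-year and can be fixed explicitly.
* Benthic PC1: PCA on standardized covariates; sign fixed so macroalgae
  loads positively (coral → macroalgae reads left to right). Percent
  change along the gradient is evaluated at the observed min/max of PC1.
* Regimes: empirical 20 %/80 % quantiles (linear interpolation) of PC1
  pooled over post-disturbance site-years; the middle 60 % never receives
  enrichment. Pre-disturbance surveys are the baseline stratum.
* Enrichment: per posterior draw on the link scale (multiplicative on
  the response), the average effect applied to all target species; with
  a zero effect every downstream number is bit-identical to the
  unenriched path (tested).
* Availability: `biomass (kg/ha) × 10 × concentration (per 100 g)`;
  percent changes are invariant to the nutrient's unit.
* Dietary metrics: RDA defaults are limited to the two published values
  used here (iron 8.4, zinc 3.6 mg/day for children under five); a 100 g
  portion is a "source" at ≥ 15 % of daily intake.
* Pairwise variation: the "Euclidean difference" of two scalar
  concentrations is the absolute difference, computed per nutrient and
  expressed as a percent of the pair mean; posterior medians (not full
  draws) enter by default. Independent draws are used across species when
  weighting assemblages (the joint posterior correlation across species
  is ignored; noted as a simplification).

## Problem sizes in the test suite

MCMC-based tests run at reduced sizes chosen once: unit-test fits use
800 kept draws after 600 warmup; coefficient-coverage uses 20 replicates
of n = 500 with 3 × 2,000 iterations; habitat-effect recovery uses 20
replicates at the ~110-sample study scale; SBC uses 200 replicates of a
30-observation model with 2 × 150 kept draws; quadratic-selection
consistency uses 10 replicates; the gamma moment check uses 2 × 10⁴
samples. The methods are identical at larger sizes; only Monte Carlo
error changes.

## Known limitations

* Plain HMC with jittered trajectories, not NUTS; strongly correlated
  posteriors need the longer trajectory setting (applied by default where
  known to matter).
* Informative trait-coefficient priors from the global marine-fish
  analysis are accepted as input but not bundled; defaults are weak and
  results will differ from an informative-prior fit (a warning says so).
* The gamma likelihood for biomass proportions has support outside (0,1];
  it is retained as specified, and no beta alternative is fitted by
  default.
* Site-year assemblage draws treat species posteriors as independent
  rather than jointly sampled.
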