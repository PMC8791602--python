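# reefnutr

Bayesian trait-based analysis of micronutrient concentrations in coral-reef
fishery species, and of how climate-driven coral-to-macroalgae regime
shifts change the nutrients those fisheries can supply.

## The problem

Coral bleaching can flip a reef from hard-coral to macroalgal dominance.
That changes which fish are present (*interspecific* effects, via species
turnover) and what individual fish tissue contains (*intraspecific*
effects, via a changed basal energy source). `reefnutr` implements the
full chain of models needed to separate and propagate both effects for
five nutrients measured per 100 g of wet muscle tissue: calcium, iron and
zinc (mg), selenium (µg), and omega-3 fatty acids (g).

## Models

**Trait model** (per nutrient): for fish sample *i*,

    y_i ~ Gamma(mu_i, k),   log mu_i = alpha_{family,site} + beta' x_i

with covariates x = (K, TL, AM, PEL, LMX) — von Bertalanffy growth
coefficient, trophic level, age at maturity, a binary pelagic-pathway
indicator, and maximum length — centered and scaled. Calcium is
log-transformed and fitted with a normal likelihood. Hierarchical
intercepts vary by taxonomic family and sampling site; an alternative
structure replaces family intercepts with species-level intercepts drawn
from a phylogenetic Gaussian process with an Ornstein–Uhlenbeck kernel,
`S_ij = eta^2 exp(-rho d_ij)`. The two structures are compared by WAIC.

**Habitat model**: on the subset of species sampled in both habitat
regimes, the linear predictor gains `beta_6,sp HAB_i` — an average
macroalgal-habitat effect with species-varying slopes (Normal(0,1) prior
on the average effect).

**Downstream**: underwater visual census (UVC) point counts (154 m², fish
≥ 8 cm, 8 replicates per site-year) are converted to biomass densities
(kg ha⁻¹) via length–weight relationships; species posterior
concentrations are biomass-weighted into reef-level assemblage
concentrations; a PCA over hard-coral cover, macroalgae cover and
structural complexity defines the benthic PC1 gradient; site-year
responses are regressed on PC1 (linear vs quadratic, chosen by WAIC);
the top/bottom 20 % of post-disturbance PC1 site-years define macroalgal
vs recovering-coral regimes; the habitat effect is sampled per posterior
draw to enrich concentrations on macroalgal reefs; and gear target lists
(trap, handline) give per-gear nutrient selectivity, total availability
(nutrient per hectare) and %-of-RDA dietary metrics.

All posteriors are sampled with the package's own Hamiltonian Monte Carlo
engine (exact analytic gradients, dual-averaging step size, warmup-adapted
diagonal mass matrix, multiple chains), with rank-normalized split-R-hat
and effective-sample-size diagnostics via arviz.

Because the study's field data are external, the package ships a
first-class synthetic-data generator (`reefnutr.synthetic`) that emulates
the study design — 44 species in 11 families, 12 sites surveyed in 1994
and 2005–2017 around a 1998 disturbance, ~40 % of sites shifting to
macroalgae, gamma-distributed tissue concentrations driven by the trait
model with a habitat effect concentrated on iron and zinc — with known
ground truth for every parameter.

## Worked example

```python
import numpy as np
from reefnutr import SyntheticConfig, apply_qc, HabitatEffectModel
from reefnutr.synthetic import generate_all

data = generate_all(SyntheticConfig(seed=1))
samples, qc = apply_qc(data["samples"])
print({n: qc.removal_fraction(n) for n in ("iron",)})
# {'iron': 0.044715447154471545}

m = HabitatEffectModel(nutrient="iron", seed=5).fit(samples, data["traits"])
print(len(m.species_), m.n_samples_, round(m.rhat_max_, 3))
# 10 103 1.003
print(round(float(np.exp(np.median(m.draws_.get("beta_HAB")))), 3))
# 1.456
```

The QC filter removed 4.5 % of iron samples (below-LOQ and upper-tail
outliers). The habitat model used the 10 species sampled in both regimes
(103 samples after QC), converged (R-hat 1.003), and estimated that
macroalgal habitat multiplies iron concentration by ×1.46 — the synthetic
ground truth is ×1.5.

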