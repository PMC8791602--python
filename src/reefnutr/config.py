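"""Configuration objects for the synthetic reef-fishery study.

The synthetic generator emulates a Seychelles-style inner-island reef
monitoring program: ~44 target species in ~11 families, 12 survey sites,
six survey years spanning a 1998 mass-bleaching disturbance, eight
replicate 154 m² point counts per site-year, and fish-tissue micronutrient
samples (calcium, iron, selenium, zinc, omega-3) whose concentrations are
driven by five scaled life-history traits plus family/site/species
intercepts and a macroalgal-habitat effect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

NUTRIENTS = ("calcium", "iron", "selenium", "zinc", "omega3")

#: concentration units, all per 100 g wet tissue
UNITS = {
    "calcium": "mg",
    "iron": "mg",
    "selenium": "ug",
    "zinc": "mg",
    "omega3": "g",
}

TRAITS = ("K", "TL", "AM", "PEL", "LMX")

FEEDING_GROUPS = (
    "browser",
    "scraper",
    "grazer",
    "invertivore",
    "mixed invertivore-piscivore",
    "piscivore",
    "planktivore",
    "corallivore",
)

#: herbivorous functional groups whose biomass share rises after regime shift
HERBIVORE_GROUPS = ("browser", "scraper", "grazer")

# Link-scale (natural log) intercepts giving field-realistic median
# concentrations: Ca ~40 mg, Fe ~1 mg, Se ~40 ug, Zn ~1.15 mg, n-3 ~0.3 g
# per 100 g wet tissue.
DEFAULT_INTERCEPTS = {
    "calcium": float(np.log(40.0)),
    "iron": 0.0,
    "selenium": float(np.log(40.0)),
    "zinc": float(np.log(1.15)),
    "omega3": float(np.log(0.3)),
}

# Modest trait effects (scaled-covariate link scale) following the
# qualitative structure reported for reef fish: selenium/omega-3 rise with
# trophic level, iron/zinc fall with it, iron rises with pelagic feeding.
DEFAULT_TRUE_BETAS = {
    "calcium": (0.20, -0.10, 0.00, 0.00, -0.15),
    "iron": (0.00, -0.15, 0.00, 0.20, 0.00),
    "selenium": (0.00, 0.30, 0.00, 0.10, -0.10),
    "zinc": (0.10, -0.25, 0.00, 0.00, -0.15),
    "omega3": (0.00, 0.25, 0.00, 0.20, 0.00),
}

# Macroalgal-habitat effect concentrated on iron and zinc (link scale).
DEFAULT_HABITAT_EFFECT = {
    "calcium": 0.0,
    "iron": float(np.log(1.5)),
    "selenium": 0.0,
    "zinc": float(np.log(1.2)),
    "omega3": 0.0,
}


@dataclass
class SyntheticConfig:
    """Ground-truth generative parameters for the synthetic study.

    All link-scale quantities use the natural-log link of the gamma /
    log-normal concentration models.
    """

    n_species: int = 44
    n_families: int = 11
    n_sites: int = 12
    years: tuple[int, ...] = (1994, 2005, 2008, 2011, 2014, 2017)
    disturbance_year: int = 1998
    n_pointcounts: int = 8
    pointcount_area_m2: float = 154.0

    # nutrient-sample design
    n_fish_per_species: int = 4
    n_dual_habitat_species: int = 10
    n_macroalgal_fish_per_dual_species: int = 7

    # trait marginals: (location, scale) on the latent scale noted in docs
    trait_means_sds: dict = field(
        default_factory=lambda: {
            "K": (float(np.log(0.3)), 0.40),
            "TL": (3.2, 0.50),
            "AM": (float(np.log(2.5)), 0.40),
            "LMX": (float(np.log(40.0)), 0.45),
        }
    )
    pel_prob: float = 0.3
    lmx_pel_latent_rho: float = 0.85  # gives point-biserial r ~ 0.66

    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    true_betas: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    true_habitat_effect: dict = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_EFFECT)
    )
    habitat_slope_sd: float = 0.05  # species deviation around average effect
    gamma_shape: dict = field(
        default_factory=lambda: {n: 10.0 for n in NUTRIENTS if n != "calcium"}
    )
    calcium_sigma: float = 0.30  # sd of log-calcium

    family_sd: float = 0.15
    site_sd: float = 0.10
    species_sd: float = 0.10
    ou_eta2: float = 0.0  # >0 switches species effects to the OU kernel
    ou_rho: float = 3.0

    # sample contamination injected for QC testing
    below_loq_fraction: float = 0.01
    outlier_fraction: float = 0.02
    outlier_multiplier: float = 8.0

    # survey structure
    regime_split: float = 0.4
    mean_fish_per_count: float = 40.0
    biomass_growth: float = 2.0  # fractional abundance growth 1994->2017
    herbivore_shift: float = 2.0  # herbivore weight multiplier, shifted reefs
    lw_a: float = 0.01
    lw_b: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        if min(self.n_species, self.n_families, self.n_sites,
               self.n_pointcounts, self.n_fish_per_species) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_species < self.n_families:
            raise ValueError("n_species must be >= n_families")
        if not 0.0 <= self.regime_split <= 1.0:
            raise ValueError("regime_split must lie in [0, 1]")
        for nutrient, k in self.gamma_shape.items():
            if k <= 0:
                raise ValueError(f"gamma_shape[{nutrient!r}] must be > 0")
        for trait, (_, scale) in self.trait_means_sds.items():
            if scale <= 0:
                raise ValueError(f"trait scale for {trait!r} must be > 0")
        if self.n_dual_habitat_species > self.n_species:
            raise ValueError("n_dual_habitat_species exceeds n_species")
        if not any(y < self.disturbance_year for y in self.years):
            raise ValueError("years must include at least one pre-disturbance year")

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["years"] = tuple(raw["years"])
        raw["trait_means_sds"] = {
            k: tuple(v) for k, v in raw["trait_means_sds"].items()
        }
        raw["true_betas"] = {k: tuple(v) for k, v in raw["true_betas"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Realized generative parameters, reproducible from (config, seed).

    Stores everything a recovery test needs: the trait coefficients and
    habitat effects actually used, the drawn family/site/species effects,
    per-site regime labels, and the derived sub-seeds.
    """

    intercepts: dict
    betas: dict
    habitat_effect: dict
    habitat_slopes: dict  # nutrient -> {species: link-scale slope}
    gamma_shape: dict
    calcium_sigma: float
    family_effects: dict  # nutrient -> {family: effect}
    site_effects: dict  # nutrient -> {site: effect}
    species_effects: dict  # nutrient -> {species: effect}
    site_regimes: dict  # site -> {"macroalgal", "recovering_coral"}
    trait_scaling: dict  # trait -> (mean, sd) used to scale covariates
    seeds: dict  # submodule name -> integer seed

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_plain(dataclasses.asdict(self)), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def derive_seeds(master_seed: int) -> dict:
    """Fixed-offset sub-seeds for each generator stage (kept below 2**31)."""
    base = int(master_seed) % (2**31 - 1013)
    return {
        "traits": base + 11,
        "phylogeny": base + 101,
        "nutrients": base + 211,
        "surveys": base + 307,
        "benthic": base + 401,
        "contamination": base + 503,
    }
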