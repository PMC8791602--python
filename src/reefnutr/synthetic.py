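"""Synthetic data generators for the reef micronutrient analysis.

Every generator is a deterministic function of (:class:`SyntheticConfig`,
seed): traits and a phylogenetic distance matrix, fish-tissue nutrient
samples following the trait-based gamma / log-normal models, and UVC +
benthic surveys with divergent post-disturbance trajectories (coral
recovery vs macroalgal regime shift).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    HERBIVORE_GROUPS,
    NUTRIENTS,
    GroundTruth,
    SyntheticConfig,
    derive_seeds,
)

__all__ = [
    "generate_traits",
    "generate_nutrient_samples",
    "generate_surveys",
    "generate_all",
]


def _species_names(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(n)]


def _family_names(n: int) -> list[str]:
    return [f"fam{i:02d}" for i in range(n)]


def _site_names(n: int) -> list[str]:
    return [f"site{i:02d}" for i in range(n)]


def generate_traits(config: SyntheticConfig):
    """Generate the species trait table and a phylogenetic distance matrix.

    Traits: growth coefficient K (yr⁻¹, log-normal), trophic level TL
    (normal, clipped to [2, 4.5]), age at maturity AM (yr, log-normal),
    maximum length LMX (cm, log-normal) and a binary pelagic-pathway
    indicator PEL. LMX and PEL are induced from a latent bivariate normal
    so their point-biserial correlation lands in the moderate 0.55–0.75
    band. Phylogenetic distances come from a latent trait-space embedding
    (family centres plus species jitter), guaranteeing that the
    exponential-decay covariance kernel built on them is positive definite.

    Returns
    -------
    traits : DataFrame
        One row per species: family, K, TL, AM, PEL, LMX, feeding_group,
        and boolean gear-target flags ``target_trap`` / ``target_handline``.
    distances : DataFrame
        Symmetric species × species matrix, zero diagonal, max distance 1.
    """
    seeds = derive_seeds(config.seed)
    rng = np.random.default_rng(seeds["traits"])
    n = config.n_species
    species = _species_names(n)
    families = _family_names(config.n_families)
    family_of = [families[i % config.n_families] for i in range(n)]

    # latent bivariate normal drives LMX (continuous) and PEL (threshold)
    rho = config.lmx_pel_latent_rho
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    mu_lmx, sd_lmx = config.trait_means_sds["LMX"]
    lmx = np.exp(mu_lmx + sd_lmx * z[:, 0])
    pel = (z[:, 1] > norm.ppf(1 - config.pel_prob)).astype(int)

    mu_k, sd_k = config.trait_means_sds["K"]
    # growth rate trades off weakly against maximum size
    k_vb = np.exp(mu_k - 0.25 * z[:, 0] + sd_k * rng.standard_normal(n))
    mu_tl, sd_tl = config.trait_means_sds["TL"]
    tl = np.clip(mu_tl + sd_tl * rng.standard_normal(n), 2.0, 4.5)
    mu_am, sd_am = config.trait_means_sds["AM"]
    am = np.exp(mu_am + 0.2 * z[:, 0] + sd_am * rng.standard_normal(n))

    feeding = _assign_feeding_groups(tl, pel, rng)
    target_trap = np.isin(
        feeding, ("browser", "scraper", "grazer", "invertivore",
                  "mixed invertivore-piscivore"),
    )
    target_handline = np.isin(
        feeding, ("mixed invertivore-piscivore", "piscivore")
    )

    traits = pd.DataFrame(
        {
            "species": species,
            "family": family_of,
            "K": k_vb,
            "TL": tl,
            "AM": am,
            "PEL": pel,
            "LMX": lmx,
            "feeding_group": feeding,
            "target_trap": target_trap,
            "target_handline": target_handline,
        }
    )

    prng = np.random.default_rng(seeds["phylogeny"])
    centres = prng.standard_normal((config.n_families, 3))
    coords = np.empty((n, 3))
    for i in range(n):
        coords[i] = centres[i % config.n_families] + 0.25 * prng.standard_normal(3)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if dist.max() > 0:
        dist = dist / dist.max()
    distances = pd.DataFrame(dist, index=species, columns=species)
    return traits, distances


def _assign_feeding_groups(tl, pel, rng):
    """Feeding group from trophic level and pathway, with some randomness."""
    groups = np.empty(len(tl), dtype=object)
    for i, (t, p) in enumerate(zip(tl, pel)):
        if t < 2.6:
            groups[i] = rng.choice(["browser", "scraper", "grazer"])
        elif t < 3.4:
            if p:
                groups[i] = rng.choice(["planktivore", "invertivore"], p=[0.6, 0.4])
            else:
                groups[i] = rng.choice(
                    ["invertivore", "corallivore"], p=[0.85, 0.15]
                )
        elif t < 3.9:
            groups[i] = "mixed invertivore-piscivore"
        else:
            groups[i] = "piscivore"
    return groups


def scale_traits(traits: pd.DataFrame, scaling: dict | None = None):
    """Center/scale the five covariates; returns (X, scaling dict).

    ``scaling`` maps trait -> (mean, sd); when None it is computed from the
    table (the convention used both in generation and model fitting).
    """
    cols = ["K", "TL", "AM", "PEL", "LMX"]
    X = traits[cols].to_numpy(float)
    if scaling is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        scaling = {c: (float(m), float(s)) for c, m, s in zip(cols, mean, sd)}
    mean = np.array([scaling[c][0] for c in cols])
    sd = np.array([scaling[c][1] for c in cols])
    return (X - mean) / sd, scaling


def generate_nutrient_samples(
    traits: pd.DataFrame,
    config: SyntheticConfig,
    distances: pd.DataFrame | None = None,
):
    """Draw fish-tissue nutrient samples from the generative trait model.

    Each fish is sampled at a random site; every fish is measured for all
    five nutrients. The first ``n_dual_habitat_species`` species (spread
    over families) also receive macroalgal-habitat fish, mimicking the
    dual-habitat subset used for the habitat (varying-slopes) model. Mean
    concentration follows the log-link linear predictor
    ``intercept + family + site + species + Xβ + β6·HAB``; gamma noise with
    per-nutrient shape k (variance μ²/k), except calcium which is
    log-normal. A small configurable fraction of rows is flagged below the
    limit of quantification or multiplied into contamination outliers so
    the QC filter has work to do.

    Returns (samples DataFrame, GroundTruth).
    """
    for k in config.gamma_shape.values():
        if k <= 0:
            raise ValueError("gamma_shape must be positive")
    seeds = derive_seeds(config.seed)
    rng = np.random.default_rng(seeds["nutrients"])
    crng = np.random.default_rng(seeds["contamination"])

    species = traits["species"].to_list()
    families = sorted(traits["family"].unique())
    sites = _site_names(config.n_sites)
    n_sp = len(species)
    Xs, scaling = scale_traits(traits)

    # random effects per nutrient
    fam_eff, site_eff, sp_eff = {}, {}, {}
    if distances is not None and config.ou_eta2 > 0:
        d = distances.loc[species, species].to_numpy(float)
        S = config.ou_eta2 * np.exp(-config.ou_rho * d) + 1e-9 * np.eye(n_sp)
        L = np.linalg.cholesky(S)
    else:
        L = None
    for nut in NUTRIENTS:
        fam_eff[nut] = dict(
            zip(families, config.family_sd * rng.standard_normal(len(families)))
        )
        site_eff[nut] = dict(
            zip(sites, config.site_sd * rng.standard_normal(len(sites)))
        )
        if L is not None:
            eff = L @ rng.standard_normal(n_sp)
        else:
            eff = config.species_sd * rng.standard_normal(n_sp)
        sp_eff[nut] = dict(zip(species, eff))

    # species-level habitat slopes around the average effect
    hab_slopes = {}
    for nut in NUTRIENTS:
        devs = config.habitat_slope_sd * rng.standard_normal(n_sp)
        hab_slopes[nut] = {
            sp: float(config.true_habitat_effect[nut] + dv)
            for sp, dv in zip(species, devs)
        }

    # dual-habitat species: one per family first, then cycle
    order = list(
        traits.sort_values(["family", "species"])
        .groupby("family", sort=True)["species"]
        .apply(list)
    )
    dual: list[str] = []
    i = 0
    while len(dual) < config.n_dual_habitat_species:
        fam_list = order[i % len(order)]
        idx = i // len(order)
        if idx < len(fam_list):
            dual.append(fam_list[idx])
        i += 1
        if i > 10 * config.n_species:
            break
    dual_set = set(dual)

    rows = []
    fish_counter = 0
    beta = {nut: np.asarray(config.true_betas[nut], float) for nut in NUTRIENTS}
    for si, sp in enumerate(species):
        fam = traits.loc[traits.species == sp, "family"].iloc[0]
        n_coral = config.n_fish_per_species
        n_ma = (
            config.n_macroalgal_fish_per_dual_species if sp in dual_set else 0
        )
        habs = ["coral"] * n_coral + ["macroalgal"] * n_ma
        for hab in habs:
            site = sites[rng.integers(len(sites))]
            fish_id = f"fish{fish_counter:04d}"
            fish_counter += 1
            for nut in NUTRIENTS:
                eta = (
                    config.intercepts[nut]
                    + fam_eff[nut][fam]
                    + site_eff[nut][site]
                    + sp_eff[nut][sp]
                    + Xs[si] @ beta[nut]
                )
                if hab == "macroalgal":
                    eta += hab_slopes[nut][sp]
                mu = np.exp(eta)
                if nut == "calcium":
                    y = np.exp(rng.normal(eta, config.calcium_sigma))
                else:
                    k = config.gamma_shape[nut]
                    y = rng.gamma(shape=k, scale=mu / k)
                rows.append(
                    {
                        "fish_id": fish_id,
                        "species": sp,
                        "family": fam,
                        "site": site,
                        "habitat": hab,
                        "year": 2019,
                        "nutrient": nut,
                        "concentration": float(y),
                        "below_loq": False,
                    }
                )
    samples = pd.DataFrame(rows)

    # contamination: below-LOQ flags and multiplicative outliers
    n_rows = len(samples)
    if config.below_loq_fraction > 0:
        loq = crng.random(n_rows) < config.below_loq_fraction
        samples.loc[loq, "below_loq"] = True
    if config.outlier_fraction > 0:
        out = crng.random(n_rows) < config.outlier_fraction
        out &= ~samples["below_loq"].to_numpy()
        samples.loc[out, "concentration"] *= config.outlier_multiplier

    truth = GroundTruth(
        intercepts=dict(config.intercepts),
        betas={n: list(map(float, beta[n])) for n in NUTRIENTS},
        habitat_effect=dict(config.true_habitat_effect),
        habitat_slopes=hab_slopes,
        gamma_shape=dict(config.gamma_shape),
        calcium_sigma=config.calcium_sigma,
        family_effects=fam_eff,
        site_effects=site_eff,
        species_effects={n: {k: float(v) for k, v in sp_eff[n].items()}
                         for n in NUTRIENTS},
        site_regimes=assign_site_regimes(config),
        trait_scaling=scaling,
        seeds=seeds,
    )
    return samples, truth


def assign_site_regimes(config: SyntheticConfig) -> dict:
    """Deterministic post-disturbance trajectory per site.

    ``round(regime_split * n_sites)`` sites take the macroalgal trajectory
    (the first sites in index order), the rest recover coral.
    """
    sites = _site_names(config.n_sites)
    n_ma = int(round(config.regime_split * config.n_sites))
    return {
        s: ("macroalgal" if i < n_ma else "recovering_coral")
        for i, s in enumerate(sites)
    }


def generate_surveys(config: SyntheticConfig, traits: pd.DataFrame):
    """Generate UVC point counts, benthic trajectories, and gear lists.

    UVC: per site-year, ``n_pointcounts`` replicate 154 m² point counts;
    within each, total fish abundance is Poisson and split over species by
    a Dirichlet-multinomial whose herbivore weights double (by default) on
    regime-shifted reefs post-disturbance; lengths are log-normal around
    45% of each species' maximum length, truncated to [8 cm, LMX]. Total
    abundance grows linearly over the survey period so that post-bleaching
    biomass (and hence nutrient availability) rises, as observed on these
    reefs. Benthic: pre-disturbance high coral everywhere; afterwards
    macroalgal-trajectory sites climb into the 33–75 % macroalgae band
    while recovery sites stay below 10 % and regain coral.

    Returns (uvc DataFrame, benthic DataFrame, gear dict).
    """
    seeds = derive_seeds(config.seed)
    rng = np.random.default_rng(seeds["surveys"])
    brng = np.random.default_rng(seeds["benthic"])
    sites = _site_names(config.n_sites)
    regimes = assign_site_regimes(config)
    species = traits["species"].to_numpy()
    lmx = traits["LMX"].to_numpy(float)
    herb = traits["feeding_group"].isin(HERBIVORE_GROUPS).to_numpy()

    base_w = rng.gamma(2.0, 1.0, size=len(species)) + 0.05
    year0, year1 = min(config.years), max(config.years)
    span = max(year1 - year0, 1)

    uvc_rows = []
    for site in sites:
        shifted = regimes[site] == "macroalgal"
        for year in config.years:
            post = year >= config.disturbance_year
            w = base_w.copy()
            if post and shifted:
                w[herb] *= config.herbivore_shift
            lam = config.mean_fish_per_count * (
                1.0 + config.biomass_growth * (year - year0) / span
            )
            for pc in range(1, config.n_pointcounts + 1):
                total = rng.poisson(lam)
                if total == 0:
                    continue
                p = rng.dirichlet(w)
                counts = rng.multinomial(total, p)
                for idx in np.nonzero(counts)[0]:
                    mean_len = 0.45 * lmx[idx]
                    length = float(
                        np.clip(
                            np.exp(np.log(mean_len) + 0.25 * rng.standard_normal()),
                            8.0,
                            max(lmx[idx], 8.0),
                        )
                    )
                    uvc_rows.append(
                        {
                            "site": site,
                            "year": year,
                            "point_count": pc,
                            "species": species[idx],
                            "length_cm": length,
                            "abundance": int(counts[idx]),
                        }
                    )
    uvc = pd.DataFrame(uvc_rows)

    benthic_rows = []
    for site in sites:
        shifted = regimes[site] == "macroalgal"
        for year in config.years:
            post = year >= config.disturbance_year
            progress = (year - config.disturbance_year) / max(
                year1 - config.disturbance_year, 1
            )
            if not post:
                coral = np.clip(brng.normal(35.0, 4.0), 15.0, 60.0)
                ma = float(np.clip(abs(brng.normal(2.0, 1.0)), 0.0, 8.0))
                sc = np.clip(brng.normal(3.5, 0.3), 2.5, 4.5)
            elif shifted:
                coral = float(np.clip(brng.normal(5.0, 2.0), 0.5, 10.0))
                ma = float(
                    np.clip(33.0 + 35.0 * progress + brng.normal(0.0, 4.0),
                            33.0, 75.0)
                )
                sc = np.clip(brng.normal(2.0, 0.25), 1.2, 2.8)
            else:
                coral = float(
                    np.clip(8.0 + 25.0 * progress + brng.normal(0.0, 3.0),
                            4.0, 45.0)
                )
                ma = float(np.clip(abs(brng.normal(2.0, 1.5)), 0.0, 9.0))
                sc = np.clip(brng.normal(3.2, 0.3), 2.2, 4.5)
            benthic_rows.append(
                {
                    "site": site,
                    "year": year,
                    "hard_coral": float(coral),
                    "macroalgae": float(ma),
                    "structural_complexity": float(sc),
                }
            )
    benthic = pd.DataFrame(benthic_rows)

    gears = {
        "trap": traits.loc[traits.target_trap, "species"].to_list(),
        "handline": traits.loc[traits.target_handline, "species"].to_list(),
    }
    return uvc, benthic, gears


def generate_all(config: SyntheticConfig):
    """Convenience wrapper producing every synthetic table in one call."""
    traits, distances = generate_traits(config)
    samples, truth = generate_nutrient_samples(traits, config, distances)
    uvc, benthic, gears = generate_surveys(config, traits)
    return {
        "traits": traits,
        "distances": distances,
        "samples": samples,
        "truth": truth,
        "uvc": uvc,
        "benthic": benthic,
        "gears": gears,
    }


def save_study(data: dict, config: SyntheticConfig, outdir) -> dict:
    """Write every synthetic table as CSV, the config as YAML, and the
    ground truth as a JSON sidecar. Returns the path of each artifact."""
    import os

    from .data_io import write_table

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name in ("traits", "samples", "uvc", "benthic"):
        paths[name] = os.path.join(outdir, f"{name}.csv")
        write_table(data[name], paths[name])
    paths["distances"] = os.path.join(outdir, "distances.csv")
    data["distances"].rename_axis("species").reset_index().to_csv(
        paths["distances"], index=False,
        float_format=lambda v: repr(float(v)))
    for gear, species in data["gears"].items():
        paths[f"gear_{gear}"] = os.path.join(outdir, f"gear_{gear}.txt")
        with open(paths[f"gear_{gear}"], "w") as fh:
            fh.write("\n".join(species) + "\n")
    paths["config"] = os.path.join(outdir, "config.yaml")
    config.to_yaml(paths["config"])
    paths["truth"] = os.path.join(outdir, "ground_truth.json")
    data["truth"].to_json(paths["truth"])
    return paths
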