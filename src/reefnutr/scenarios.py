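"""Regime assignment, habitat enrichment, gear selectivity, availability.

The habitat (varying-slopes) model's average macroalgal effect is
propagated onto regime-shifted reefs: site-years in the top 20% of the
benthic PC1 gradient are "macroalgal", the bottom 20% "recovering coral",
and the middle 60% receives no intraspecific correction. Enrichment is
applied per posterior draw on the link scale (multiplicative on the
response), so uncertainty in the effect size carries through to every
downstream metric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .mcmc import summarize

__all__ = [
    "assign_regimes",
    "apply_enrichment",
    "regime_contrast",
    "gear_selectivity",
    "availability",
    "dietary_contribution",
    "DEFAULT_RDA",
]

#: recommended dietary allowances for children under 5 (mg per day)
DEFAULT_RDA = {"iron": 8.4, "zinc": 3.6}

#: a 100 g portion counts as a nutrient source at >= 15% of daily intake
SOURCE_THRESHOLD_PCT = 15.0


def assign_regimes(
    gradient_scores: pd.DataFrame,
    disturbance_year: int = 1998,
    quantile: float = 0.20,
) -> pd.DataFrame:
    """Label each site-year with its habitat regime.

    Site-years before the disturbance are ``pre_bleaching``. Quantile cut
    points are computed over the pooled post-disturbance site-years
    (empirical quantiles, linear interpolation): the top ``quantile``
    of PC1 is ``macroalgal``, the bottom ``quantile`` is
    ``recovering_coral``, and the rest ``intermediate``.
    """
    df = gradient_scores.copy().sort_values(["site", "year"]).reset_index(
        drop=True)
    post = df[df["year"] >= disturbance_year]
    if len(post) < 5:
        raise ValueError("need at least 5 post-disturbance site-years")
    pc1 = post["pc1"].to_numpy(float)
    if np.ptp(pc1) == 0:
        raise ValueError("degenerate benthic gradient: all PC1 equal")
    lo = np.quantile(pc1, quantile)
    hi = np.quantile(pc1, 1.0 - quantile)
    regime = []
    for _, row in df.iterrows():
        if row["year"] < disturbance_year:
            regime.append("pre_bleaching")
        elif row["pc1"] >= hi:
            regime.append("macroalgal")
        elif row["pc1"] <= lo:
            regime.append("recovering_coral")
        else:
            regime.append("intermediate")
    df["regime"] = regime
    post_mask = df["year"] >= disturbance_year
    df["quantile_rank"] = np.nan
    ranks = df.loc[post_mask, "pc1"].rank(pct=True, method="average")
    df.loc[post_mask, "quantile_rank"] = ranks
    return df


def apply_enrichment(
    conc_draws: pd.DataFrame,
    beta6_draws: np.ndarray | None,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrich species concentration draws by the habitat effect.

    Per draw, the link-scale average effect β₆ sampled from its posterior
    multiplies the response by ``exp(β₆)``; the same β₆ draw applies to
    every species in that row (the average effect is taken as
    representative of all target species). ``beta6_draws=None`` passes the
    input through unchanged with a warning.
    """
    if beta6_draws is None:
        warnings.warn("no habitat-effect draws; concentrations unchanged",
                      stacklevel=2)
        return conc_draws
    b = np.asarray(beta6_draws, float).reshape(-1)
    n = len(conc_draws)
    if len(b) == n:
        pick = b
    else:
        rng = np.random.default_rng(seed)
        pick = b[rng.integers(len(b), size=n)]
    return conc_draws.mul(np.exp(pick), axis=0)


def regime_contrast(
    profiles_plain: pd.DataFrame,
    profiles_enriched: pd.DataFrame,
    regimes: pd.DataFrame,
    value: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent change on macroalgal reefs relative to the pre-bleaching mean.

    ``profiles_*`` are reef nutrient profiles (site, year, nutrient,
    median, ...) computed without and with habitat enrichment. The
    baseline per nutrient is the across-reef mean of pre-bleaching
    site-years (computed from the plain profile). Returns per macroalgal
    site-year the composition-only ("interspecific") and
    composition+enrichment ("intraspecific") percent changes, plus
    per-nutrient medians across reefs.
    """
    reg = regimes.set_index(["site", "year"])["regime"]
    pre = profiles_plain.join(reg, on=["site", "year"])
    pre = pre[pre["regime"] == "pre_bleaching"]
    if pre.empty:
        raise ValueError("no pre-bleaching surveys; baseline undefined")
    baseline = pre.groupby("nutrient")[value].mean()

    rows = []
    for label, prof in (("interspecific", profiles_plain),
                        ("intraspecific", profiles_enriched)):
        d = prof.join(reg, on=["site", "year"])
        d = d[d["regime"] == "macroalgal"]
        for _, r in d.iterrows():
            base = baseline[r["nutrient"]]
            rows.append({
                "site": r["site"],
                "year": r["year"],
                "nutrient": r["nutrient"],
                "effect": label,
                "value": r[value],
                "baseline": base,
                "percent_change": 100.0 * (r[value] - base) / base,
            })
    out = pd.DataFrame(rows)
    medians = (out.groupby(["nutrient", "effect"])["percent_change"]
               .median().rename("median_percent_change").reset_index())
    return out, medians


def gear_selectivity(
    biomass: pd.DataFrame,
    conc_draws_by_nutrient: dict,
    gear_lists: dict,
    regimes: pd.DataFrame,
    beta6_draws_by_nutrient: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biomass-weighted nutrient concentration of each gear's target species.

    Computed per gear × site-year; on macroalgal site-years, species
    concentrations are first enriched by the habitat effect (when draws
    are provided). Stratum summaries (mean ± 2 SEM across reef sites
    within regime-year) are returned alongside.
    """
    for gear, species in gear_lists.items():
        if not species:
            raise ValueError(f"gear {gear!r} has an empty target list")
    reg = regimes.set_index(["site", "year"])["regime"]
    rows = []
    for nutrient, conc in conc_draws_by_nutrient.items():
        enriched = conc
        if beta6_draws_by_nutrient and nutrient in beta6_draws_by_nutrient:
            enriched = apply_enrichment(
                conc, beta6_draws_by_nutrient[nutrient], seed=seed)
        for gear, species in gear_lists.items():
            targets = [s for s in species if s in conc.columns]
            if not targets:
                raise ValueError(
                    f"no posterior draws for any {gear!r} target species")
            for (site, year), grp in biomass.groupby(["site", "year"]):
                regime = reg.get((site, year), "intermediate")
                use = enriched if regime == "macroalgal" else conc
                w = (grp[grp["species"].isin(targets)]
                     .groupby("species")["biomass_kg_ha"].sum())
                if w.sum() == 0:
                    continue
                d = use[w.index].to_numpy() @ (w.to_numpy() / w.sum())
                rows.append({
                    "gear": gear, "site": site, "year": year,
                    "regime": regime, "nutrient": nutrient,
                    "concentration": float(np.median(d)),
                })
    table = pd.DataFrame(rows)
    strata = []
    for (gear, regime, year, nutrient), grp in table.groupby(
            ["gear", "regime", "year", "nutrient"]):
        vals = grp["concentration"].to_numpy(float)
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        strata.append({
            "gear": gear, "regime": regime, "year": year,
            "nutrient": nutrient, "n_sites": len(vals),
            "mean": float(vals.mean()),
            "sem2_low": float(vals.mean() - 2 * sem),
            "sem2_high": float(vals.mean() + 2 * sem),
        })
    return table, pd.DataFrame(strata)


#: 1 kg of fish = 10 portions of 100 g
PORTIONS_PER_KG = 10.0


def availability(
    biomass: pd.DataFrame,
    conc_draws_by_nutrient: dict,
    regimes: pd.DataFrame,
    target_species: list[str] | None = None,
    beta6_draws_by_nutrient: dict | None = None,
    baseline_year: int = 1994,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total fishable nutrient quantity per hectare, per site-year.

    ``availability = Σ_species biomass (kg ha⁻¹) × 10 × concentration
    (per 100 g)`` — so mg-per-100 g nutrients yield mg ha⁻¹. On macroalgal
    site-years, concentrations are enriched when habitat-effect draws are
    supplied. The trend table reports the percent change of each
    regime-group mean relative to the baseline-year mean.
    """
    reg = regimes.set_index(["site", "year"])["regime"]
    rows = []
    for nutrient, conc in conc_draws_by_nutrient.items():
        targets = (set(target_species) if target_species is not None
                   else set(conc.columns))
        enriched = conc
        if beta6_draws_by_nutrient and nutrient in beta6_draws_by_nutrient:
            enriched = apply_enrichment(
                conc, beta6_draws_by_nutrient[nutrient], seed=seed)
        for (site, year), grp in biomass.groupby(["site", "year"]):
            regime = reg.get((site, year), "intermediate")
            use = enriched if regime == "macroalgal" else conc
            w = (grp[grp["species"].isin(targets)]
                 .groupby("species")["biomass_kg_ha"].sum())
            missing = set(w.index) - set(use.columns)
            if missing:
                raise ValueError(
                    f"no posterior draws for species {sorted(missing)}")
            draws = use[w.index].to_numpy() @ (w.to_numpy()
                                               * PORTIONS_PER_KG)
            row = {"site": site, "year": year, "nutrient": nutrient,
                   "regime": regime}
            row.update(summarize(draws))
            rows.append(row)
    table = pd.DataFrame(rows)

    # long-term trend: percent change of regime-group means vs baseline year
    base = table[table["year"] == baseline_year]
    if base.empty:
        raise ValueError(f"no surveys in baseline year {baseline_year}")
    base_mean = base.groupby("nutrient")["median"].mean()
    trend_rows = []
    post = table[table["year"] != baseline_year]
    for (nutrient, regime, year), grp in post.groupby(
            ["nutrient", "regime", "year"]):
        b = base_mean[nutrient]
        m = grp["median"].mean()
        trend_rows.append({
            "nutrient": nutrient, "regime": regime, "year": year,
            "mean_availability": float(m),
            "baseline_mean": float(b),
            "percent_change": float(100.0 * (m - b) / b),
        })
    return table, pd.DataFrame(trend_rows)


def dietary_contribution(
    concentrations: dict,
    rda_table: dict | None = None,
) -> pd.DataFrame:
    """Percent of the daily recommended allowance in a 100 g portion.

    ``concentrations`` maps nutrient → concentration per 100 g (same unit
    as the RDA). A portion is classified as a nutrient source when it
    provides at least 15% of the daily requirement.
    """
    rda_table = rda_table or DEFAULT_RDA
    rows = []
    for nutrient, conc in concentrations.items():
        if nutrient not in rda_table:
            continue
        rda = rda_table[nutrient]
        if rda <= 0:
            raise ValueError(f"RDA for {nutrient!r} must be positive")
        pct = 100.0 * conc / rda
        rows.append({
            "nutrient": nutrient,
            "portion_g": 100.0,
            "concentration_per_100g": float(conc),
            "rda_per_day": float(rda),
            "pct_rda_per_portion": float(pct),
            "is_source": bool(pct >= SOURCE_THRESHOLD_PCT),
        })
    return pd.DataFrame(rows)
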