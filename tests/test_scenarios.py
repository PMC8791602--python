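"""Regime assignment, enrichment propagation, selectivity, availability."""

import numpy as np
import pandas as pd
import pytest

from reefnutr.scenarios import (
    apply_enrichment,
    assign_regimes,
    availability,
    dietary_contribution,
    gear_selectivity,
    regime_contrast,
)


def _scores(pc1_by_site_year):
    rows = [{"site": s, "year": y, "pc1": v}
            for (s, y), v in pc1_by_site_year.items()]
    return pd.DataFrame(rows)


class TestAssignRegimes:
    def test_quantile_arithmetic_on_1_to_10(self):
        scores = _scores({(f"s{i}", 2005): float(i) for i in range(1, 11)})
        out = assign_regimes(scores).set_index("site")
        ma = set(out[out.regime == "macroalgal"].index)
        rec = set(out[out.regime == "recovering_coral"].index)
        assert ma == {"s9", "s10"}
        assert rec == {"s1", "s2"}
        assert (out.loc[[f"s{i}" for i in range(3, 9)],
                        "regime"] == "intermediate").all()

    def test_pre_disturbance_years_labelled(self):
        scores = _scores({(f"s{i}", 2005): float(i) for i in range(1, 8)})
        scores = pd.concat([
            scores,
            _scores({("s1", 1994): 0.0, ("s2", 1994): 9.0}),
        ], ignore_index=True)
        out = assign_regimes(scores)
        pre = out[out.year == 1994]
        assert (pre["regime"] == "pre_bleaching").all()

    def test_degenerate_gradient_refused(self):
        scores = _scores({(f"s{i}", 2005): 1.0 for i in range(8)})
        with pytest.raises(ValueError, match="degenerate"):
            assign_regimes(scores)

    def test_too_few_post_site_years_refused(self):
        scores = _scores({(f"s{i}", 2005): float(i) for i in range(4)})
        with pytest.raises(ValueError, match="at least 5"):
            assign_regimes(scores)

    def test_partition_is_20_60_20_within_rounding(self):
        rng = np.random.default_rng(5)
        scores = _scores({(f"s{i}", y): float(rng.normal())
                          for i in range(12)
                          for y in (2005, 2008, 2011, 2014, 2017)})
        out = assign_regimes(scores)
        post = out[out.year >= 1998]
        counts = post["regime"].value_counts()
        n = len(post)
        assert abs(counts.get("macroalgal", 0) - 0.2 * n) <= 2
        assert abs(counts.get("recovering_coral", 0) - 0.2 * n) <= 2
        assert abs(counts.get("intermediate", 0) - 0.6 * n) <= 4

    def test_macroalgal_assignments_match_ground_truth_sites(self, study):
        """Top-quantile PC1 site-years fall on the regime-shifted sites."""
        from reefnutr.assemblage import benthic_pca

        g = benthic_pca(study["benthic"])
        out = assign_regimes(g.scores)
        truth = study["truth"].site_regimes
        ma = out[out.regime == "macroalgal"]
        assert len(ma) > 0
        frac = (ma["site"].map(truth) == "macroalgal").mean()
        assert frac >= 0.95


class TestApplyEnrichment:
    def test_zero_effect_is_bit_identical(self):
        rng = np.random.default_rng(0)
        conc = pd.DataFrame({"spA": rng.gamma(2, 1, 100),
                             "spB": rng.gamma(2, 1, 100)})
        out = apply_enrichment(conc, np.zeros(100))
        assert np.array_equal(out.to_numpy(), conc.to_numpy())

    def test_log2_effect_doubles_concentration(self):
        conc = pd.DataFrame({"spA": np.full(50, 2.0)})
        out = apply_enrichment(conc, np.full(50, np.log(2.0)))
        assert np.allclose(out["spA"], 4.0, rtol=1e-12)

    def test_missing_draws_pass_through_with_warning(self):
        conc = pd.DataFrame({"spA": np.full(10, 2.0)})
        with pytest.warns(UserWarning, match="unchanged"):
            out = apply_enrichment(conc, None)
        assert out is conc

    def test_uncertainty_propagates_per_draw(self):
        rng = np.random.default_rng(3)
        conc = pd.DataFrame({"spA": np.ones(4000)})
        b6 = rng.normal(0.4, 0.1, 4000)
        out = apply_enrichment(conc, b6)
        assert out["spA"].std() > 0
        assert np.median(out["spA"]) == pytest.approx(np.exp(0.4), rel=0.02)


def _profiles(values):
    rows = []
    for (site, year, nutrient), v in values.items():
        rows.append({"site": site, "year": year, "nutrient": nutrient,
                     "median": v})
    return pd.DataFrame(rows)


def _regimes(labels):
    return pd.DataFrame([{"site": s, "year": y, "regime": r, "pc1": 0.0}
                         for (s, y), r in labels.items()])


class TestRegimeContrast:
    def test_identity_gives_exact_zero(self):
        prof = _profiles({("s1", 1994, "iron"): 1.0,
                          ("s2", 2017, "iron"): 1.0})
        reg = _regimes({("s1", 1994): "pre_bleaching",
                        ("s2", 2017): "macroalgal"})
        out, medians = regime_contrast(prof, prof.copy(), reg)
        assert (out["percent_change"] == 0.0).all()
        assert (medians["median_percent_change"] == 0.0).all()

    def test_iron_style_arithmetic(self):
        """Composition-only 1.0 vs enriched 1.57 on a baseline of 1.0 gives
        +0% interspecific and +57% intraspecific contrasts."""
        plain = _profiles({("s1", 1994, "iron"): 1.0,
                           ("s2", 2017, "iron"): 1.0})
        enriched = _profiles({("s1", 1994, "iron"): 1.0,
                              ("s2", 2017, "iron"): 1.57})
        reg = _regimes({("s1", 1994): "pre_bleaching",
                        ("s2", 2017): "macroalgal"})
        _, medians = regime_contrast(plain, enriched, reg)
        m = medians.set_index("effect")["median_percent_change"]
        assert m["interspecific"] == pytest.approx(0.0)
        assert m["intraspecific"] == pytest.approx(57.0)

    def test_missing_pre_bleaching_refused(self):
        prof = _profiles({("s2", 2017, "iron"): 1.0})
        reg = _regimes({("s2", 2017): "macroalgal"})
        with pytest.raises(ValueError, match="pre-bleaching"):
            regime_contrast(prof, prof, reg)


def _biomass(rows):
    return pd.DataFrame(rows, columns=["site", "year", "species",
                                       "biomass_kg_ha"])


def _const_draws(conc, n=50):
    return pd.DataFrame({sp: np.full(n, v) for sp, v in conc.items()})


class TestGearSelectivity:
    def test_two_species_equal_biomass(self):
        biomass = _biomass([("s1", 2005, "spA", 2.0),
                            ("s1", 2005, "spB", 2.0)])
        reg = _regimes({("s1", 2005): "intermediate"})
        table, strata = gear_selectivity(
            biomass, {"iron": _const_draws({"spA": 1.0, "spB": 3.0})},
            {"trap": ["spA", "spB"]}, reg)
        assert table["concentration"].iloc[0] == pytest.approx(2.0)

    def test_identical_target_lists_identical_selectivity(self):
        biomass = _biomass([("s1", 2005, "spA", 1.0),
                            ("s1", 2005, "spB", 4.0)])
        reg = _regimes({("s1", 2005): "intermediate"})
        conc = {"iron": _const_draws({"spA": 1.0, "spB": 3.0})}
        table, _ = gear_selectivity(
            biomass, conc, {"trap": ["spA", "spB"],
                            "handline": ["spA", "spB"]}, reg)
        vals = table.set_index("gear")["concentration"]
        assert vals["trap"] == vals["handline"]

    def test_all_species_gear_equals_assemblage_concentration(self):
        from reefnutr.assemblage import assemblage_concentration_draws

        rng = np.random.default_rng(7)
        conc = pd.DataFrame({s: rng.gamma(3, 1, 200)
                             for s in ("spA", "spB", "spC")})
        biomass = _biomass([("s1", 2005, "spA", 1.0),
                            ("s1", 2005, "spB", 5.0),
                            ("s1", 2005, "spC", 2.0)])
        reg = _regimes({("s1", 2005): "intermediate"})
        table, _ = gear_selectivity(
            biomass, {"iron": conc},
            {"trap": ["spA", "spB", "spC"]}, reg)
        draws, _ = assemblage_concentration_draws(biomass, conc)
        assert table["concentration"].iloc[0] == pytest.approx(
            float(np.median(draws[("s1", 2005)])))

    def test_empty_gear_list_rejected(self):
        biomass = _biomass([("s1", 2005, "spA", 1.0)])
        reg = _regimes({("s1", 2005): "intermediate"})
        with pytest.raises(ValueError, match="empty"):
            gear_selectivity(biomass, {"iron": _const_draws({"spA": 1.0})},
                             {"trap": []}, reg)

    def test_trophic_targeting_orders_selenium(self, study):
        """Handlines target higher-trophic species; selenium rises with
        trophic level, so handline selectivity exceeds trap selectivity."""
        truth = study["truth"]
        traits = study["traits"].set_index("species")
        from reefnutr.synthetic import scale_traits

        Xs, _ = scale_traits(study["traits"], truth.trait_scaling)
        beta = np.asarray(truth.betas["selenium"])
        conc = pd.DataFrame({
            sp: np.full(20, np.exp(truth.intercepts["selenium"]
                                   + Xs[i] @ beta))
            for i, sp in enumerate(study["traits"]["species"])
        })
        from reefnutr.assemblage import biomass_density

        biomass = biomass_density(study["uvc"], n_replicates=8)
        reg = assign_regimes(
            __import__("reefnutr.assemblage", fromlist=["benthic_pca"])
            .benthic_pca(study["benthic"]).scores)
        table, _ = gear_selectivity(biomass, {"selenium": conc},
                                    study["gears"], reg)
        means = table.groupby("gear")["concentration"].mean()
        assert means["handline"] > means["trap"]

    def test_enrichment_applied_only_on_macroalgal_reefs(self):
        biomass = _biomass([("ma", 2017, "spA", 1.0),
                            ("hc", 2017, "spA", 1.0)])
        reg = _regimes({("ma", 2017): "macroalgal",
                        ("hc", 2017): "recovering_coral"})
        conc = {"iron": _const_draws({"spA": 2.0})}
        b6 = {"iron": np.full(50, np.log(2.0))}
        table, _ = gear_selectivity(biomass, conc, {"trap": ["spA"]}, reg,
                                    beta6_draws_by_nutrient=b6)
        vals = table.set_index("site")["concentration"]
        assert vals["ma"] == pytest.approx(4.0)
        assert vals["hc"] == pytest.approx(2.0)


class TestAvailability:
    def _setup(self, biomass_val=100.0, conc_val=1.0):
        biomass = _biomass([("s1", 1994, "spA", biomass_val),
                            ("s1", 2017, "spA", biomass_val)])
        reg = _regimes({("s1", 1994): "pre_bleaching",
                        ("s1", 2017): "recovering_coral"})
        conc = {"iron": _const_draws({"spA": conc_val})}
        return biomass, conc, reg

    def test_unit_conversion(self):
        biomass, conc, reg = self._setup()
        table, _ = availability(biomass, conc, reg)
        # 100 kg/ha = 1000 x 100 g portions; 1 mg each -> 1000 mg/ha
        assert table["median"].iloc[0] == pytest.approx(1000.0)

    def test_linearity_in_biomass(self):
        b1, conc, reg = self._setup(100.0)
        b2, _, _ = self._setup(200.0)
        t1, _ = availability(b1, conc, reg)
        t2, _ = availability(b2, conc, reg)
        assert np.allclose(t2["median"], 2 * t1["median"])

    def test_percent_change_arithmetic(self):
        biomass = _biomass([("s1", 1994, "spA", 100.0),
                            ("s1", 2017, "spA", 318.0)])
        reg = _regimes({("s1", 1994): "pre_bleaching",
                        ("s1", 2017): "recovering_coral"})
        conc = {"iron": _const_draws({"spA": 1.0})}
        _, trend = availability(biomass, conc, reg)
        assert trend["percent_change"].iloc[0] == pytest.approx(218.0)

    def test_percent_change_invariant_to_units(self):
        biomass, conc_mg, reg = self._setup(conc_val=1.0)
        conc_ug = {"iron": _const_draws({"spA": 1000.0})}  # mg -> ug
        _, t_mg = availability(biomass, conc_mg, reg)
        _, t_ug = availability(biomass, conc_ug, reg)
        assert np.allclose(t_mg["percent_change"], t_ug["percent_change"])

    def test_additivity_over_species(self):
        biomass = _biomass([("s1", 1994, "spA", 50.0),
                            ("s1", 1994, "spB", 70.0),
                            ("s1", 2017, "spA", 1.0)])
        reg = _regimes({("s1", 1994): "pre_bleaching",
                        ("s1", 2017): "intermediate"})
        conc = {"iron": _const_draws({"spA": 1.0, "spB": 2.0})}
        table, _ = availability(biomass, conc, reg)
        total = table.set_index("year").loc[1994, "median"]
        only_a, _ = availability(
            biomass[biomass.species == "spA"], conc, reg)
        only_b, _ = availability(
            biomass[biomass.species == "spB"], conc, reg)
        a = only_a.set_index("year").loc[1994, "median"]
        b = only_b.set_index("year").loc[1994, "median"]
        assert total == pytest.approx(a + b)


class TestDietaryContribution:
    def test_full_rda_is_100_percent(self):
        out = dietary_contribution({"iron": 8.4})
        assert out["pct_rda_per_portion"].iloc[0] == pytest.approx(100.0)
        assert out["is_source"].iloc[0]

    def test_zero_concentration_not_a_source(self):
        out = dietary_contribution({"iron": 0.0})
        assert out["pct_rda_per_portion"].iloc[0] == 0.0
        assert not out["is_source"].iloc[0]

    def test_zinc_inverse_of_printed_percentage(self):
        # 1.152 mg per 100 g at an RDA of 3.6 mg/day is exactly 32%
        out = dietary_contribution({"zinc": 1.152})
        assert out["pct_rda_per_portion"].iloc[0] == pytest.approx(32.0)
        assert out["is_source"].iloc[0]

    def test_nonpositive_rda_rejected(self):
        with pytest.raises(ValueError):
            dietary_contribution({"iron": 1.0}, {"iron": 0.0})

    def test_threshold_classification(self):
        out = dietary_contribution({"zinc": 0.54})  # exactly 15%
        assert out["is_source"].iloc[0]
        out2 = dietary_contribution({"zinc": 0.53})
        assert not out2["is_source"].iloc[0]
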