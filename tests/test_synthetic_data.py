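import numpy as np
import pandas as pd
import pytest

import reefranges as rr
from reefranges.schema import TRAIT_LEVELS
from reefranges.synthetic_data import ConfigError, PoolConfig, BiasConfig, EffectConfig


class TestSpeciesPool:
    def test_pool_size_and_determinism(self, pool):
        assert len(pool) == 497
        again = rr.make_species_pool(rr.default_pool_config(seed=1))
        pd.testing.assert_frame_equal(pool, again)

    def test_taxonomy_is_properly_nested(self, pool):
        assert (pool.groupby("genus")["family"].nunique() == 1).all()
        assert (pool.groupby("family")["order"].nunique() == 1).all()

    def test_degenerate_probability_forces_level(self):
        cfg = PoolConfig(
            n_species=50,
            trait_level_probs={"spawning_mode": {"pelagic": 1.0, "nonpelagic": 0.0}},
            seed=0,
        )
        pool = rr.make_species_pool(cfg)
        assert (pool["spawning_mode"] == "pelagic").all()

    def test_trait_proportions_match_config(self):
        # binomial-SE oracle at n = 10,000
        n = 10_000
        pool = rr.make_species_pool(PoolConfig(n_species=n, seed=11))
        for trait, probs in rr.default_pool_config().trait_level_probs.items():
            for level, p in probs.items():
                se = np.sqrt(p * (1 - p) / n)
                obs = (pool[trait] == level).mean()
                assert abs(obs - p) < 3 * se + 1e-12, (trait, level, obs, p)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ConfigError):
            rr.make_species_pool(PoolConfig(
                trait_level_probs={"spawning_mode": {"pelagic": 0.7, "nonpelagic": 0.7}}
            ))
        with pytest.raises(ConfigError):
            rr.make_species_pool(PoolConfig(n_species=5))


class TestRangeSimulation:
    def test_no_effects_no_noise_gives_half_d_ref(self, pool):
        eff = EffectConfig(beta={}, sigma_order=0, sigma_family=0, sigma_genus=0,
                           sigma_basin=0, sigma_structure=0, sigma_resid=0, d_ref=6000.0)
        out = rr.simulate_range_sizes(pool, eff, seed=0)
        np.testing.assert_allclose(out["range_km"], 3000.0)
        np.testing.assert_allclose(out["y_logit"], 0.0, atol=1e-12)

    def test_single_beta_forces_exact_group_difference(self, pool):
        eff = EffectConfig(beta={"spawning_pelagic": 1.0}, sigma_order=0, sigma_family=0,
                           sigma_genus=0, sigma_basin=0, sigma_structure=0,
                           sigma_resid=0, d_ref=6000.0)
        out = rr.simulate_range_sizes(pool, eff, seed=0)
        y = out["y_logit"].to_numpy()
        pel = pool["spawning_mode"].eq("pelagic").to_numpy()
        assert y[pel].mean() - y[~pel].mean() == pytest.approx(1.0)

    def test_bounds_strictly_inside(self, ranges):
        assert (ranges["range_km"] > 0).all()
        assert (ranges["range_km"] < 6000.0).all()

    def test_family_intraclass_correlation(self):
        # variance-decomposition oracle: y = u_family + e, ICC = s^2/(s^2+r^2)
        s, r = 0.8, 1.0
        cfg = PoolConfig(n_species=300, n_orders=2, families_per_order=10,
                         genera_per_family=2, seed=3)
        pool = rr.make_species_pool(cfg)
        eff = EffectConfig(beta={}, sigma_order=0, sigma_family=s, sigma_genus=0,
                           sigma_basin=0, sigma_structure=0, sigma_resid=r)
        iccs = []
        for rep in range(200):
            y = rr.simulate_range_sizes(pool, eff, seed=rep)["y_logit"].to_numpy()
            fam = pool["family"].to_numpy()
            grand = y.mean()
            between = np.var([y[fam == f].mean() for f in np.unique(fam)], ddof=0)
            within = np.mean([np.var(y[fam == f], ddof=0) for f in np.unique(fam)])
            iccs.append(between / (between + within))
        expected = s**2 / (s**2 + r**2)
        # between-group variance of group means includes within/group-size noise;
        # tolerate that upward bias plus Monte-Carlo error
        assert np.mean(iccs) == pytest.approx(expected, abs=0.08)

    def test_unknown_beta_term_rejected(self, pool):
        with pytest.raises(ConfigError):
            rr.simulate_range_sizes(pool, EffectConfig(beta={"bogus": 1.0}), seed=0)


class TestOccurrences:
    def test_assigned_ranges_recovered_exactly(self, pool, ranges):
        occ = rr.simulate_occurrences(pool, ranges, rr.default_tep_geometry(), seed=4)
        rt = rr.range_table(occ, d_ref_km=6000.0)
        merged = ranges.merge(rt, on="species_id")
        rel = np.abs(merged["range_km_y"] - merged["range_km_x"]) / merged["range_km_x"]
        assert rel.max() < 0.01

    def test_zero_range_species_collapse_to_point(self, pool):
        zero = pd.DataFrame({"species_id": pool["species_id"],
                             "range_km": 0.0, "y_logit": np.nan})
        occ = rr.simulate_occurrences(pool.head(3), zero.head(3),
                                      rr.default_tep_geometry(), seed=0)
        for _, grp in occ.groupby("species_id"):
            assert rr.max_linear_distance(grp["lon"], grp["lat"]) == 0.0

    def test_oversized_range_names_species(self, pool):
        big = pd.DataFrame({"species_id": pool["species_id"].head(1),
                            "range_km": 9000.0, "y_logit": np.nan})
        with pytest.raises(ValueError, match="sp0000"):
            rr.simulate_occurrences(pool.head(1), big, rr.default_tep_geometry(), seed=0)

    def test_basin_scale_ranges_representable(self, pool, ranges):
        # d_ref = 6,000 km ranges fit on the ~6,060 km coastline geometry
        assert ranges["range_km"].max() < rr.default_tep_geometry().max_span_km


class TestFocalSubset:
    def test_exact_subset_size_and_determinism(self, species_focal, pool):
        assert species_focal["in_focal_subset"].sum() == 148
        again = rr.assign_focal_subset(pool, rr.headline_bias_config(), seed=3)
        pd.testing.assert_frame_equal(species_focal, again)

    def test_flagged_species_get_pld(self, species_focal):
        flagged = species_focal["in_focal_subset"]
        assert species_focal.loc[flagged, "pld_days"].notna().all()
        assert species_focal.loc[~flagged, "pld_days"].isna().all()

    def test_all_levels_present_in_subset(self, species_focal):
        sub = species_focal[species_focal["in_focal_subset"]]
        for trait, levels in TRAIT_LEVELS.items():
            assert set(sub[trait]) == set(levels), trait

    def test_zero_bias_is_unbiased(self, pool):
        # flagged pelagic proportion fluctuates around the pool proportion
        props = []
        for seed in range(60):
            out = rr.assign_focal_subset(pool, BiasConfig(subset_size=148), seed=seed)
            sub = out[out["in_focal_subset"]]
            props.append((sub["spawning_mode"] == "pelagic").mean())
        pool_prop = (pool["spawning_mode"] == "pelagic").mean()
        assert abs(np.mean(props) - pool_prop) < 0.02

    def test_pelagic_bias_overrepresents_pelagic(self, pool):
        # Monte-Carlo oracle: log-odds +2 inflates the flagged pelagic share
        bias = BiasConfig(subset_size=148,
                          gamma={"intercept": -3.0, "spawning_pelagic": 2.0})
        pool_prop = (pool["spawning_mode"] == "pelagic").mean()
        hits = 0
        for seed in range(200):
            out = rr.assign_focal_subset(pool, bias, seed=seed)
            sub = out[out["in_focal_subset"]]
            hits += (sub["spawning_mode"] == "pelagic").mean() > pool_prop
        assert hits >= 198

    def test_infeasible_subset_rejected(self, pool):
        with pytest.raises(ConfigError):
            rr.assign_focal_subset(pool, BiasConfig(subset_size=5000), seed=0)
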