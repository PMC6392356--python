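import numpy as np
import pandas as pd
import pytest

import reefranges as rr
from reefranges import lmm
from reefranges.trait_model import (
    ModelSpec, FittedModel, _INTERACTION, akaike_weights, build_design,
    compute_vif, enumerate_submodels, model_average, standardize_predictors,
)


class TestStandardize:
    def test_continuous_scaled_to_half_sd(self):
        df = pd.DataFrame({"x": [0.0, 4.0] * 10})
        out = standardize_predictors(df, continuous_names=("x",))
        assert out["x"].std(ddof=1) == pytest.approx(0.5)
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_binary_centred(self):
        df = pd.DataFrame({"b": ["no", "yes", "yes", "no", "yes"]})
        out = standardize_predictors(df, binary_names=("b",),
                                     factor_levels={"b": ("no", "yes")})
        assert out["b_yes"].mean() == pytest.approx(0.0, abs=1e-12)
        assert set(np.round(np.unique(out["b_yes"]), 6)) == {-0.6, 0.4}

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize_predictors(pd.DataFrame({"x": [1.0] * 5}),
                                   continuous_names=("x",))

    def test_reference_levels_carry_no_column(self, pool, ranges):
        _, X, _ = build_design(pool, ranges, d_ref_km=6000.0)
        for ref_col in ("spawning_nonpelagic", "mobility_low",
                        "circadian_diurnal", "aggregation_nonaggregative"):
            assert ref_col not in X.columns
        assert {"spawning_pelagic", "mobility_medium", "mobility_high",
                "circadian_nocturnal", "aggregation_aggregative"} <= set(X.columns)


class TestVIF:
    def test_orthogonal_predictors_give_unity(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        vif = compute_vif(X)
        np.testing.assert_allclose(vif.values, 1.0, atol=1e-10)

    def test_near_collinear_flagged(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=200)
        X = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 1e-3, 200),
                          "x3": rng.normal(size=200)})
        vif = compute_vif(X)
        assert vif["x1"] > 2.5 and vif["x2"] > 2.5
        assert vif["x3"] < 2.5

    def test_rank_deficient_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x1|x2"):
            compute_vif(X)


class TestEnumeration:
    @pytest.mark.parametrize("terms,expected", [
        (("body_size", "circadian"), 4),                       # 2^2
        (("spawning", "mobility", _INTERACTION), 5),           # 4 + 1
        (("body_size", "spawning", "mobility", "circadian", "aggregation",
          _INTERACTION), 40),                                  # 2^5 + 2^3
        (("body_size", "spawning", "mobility", "circadian", "aggregation",
          "pld", _INTERACTION), 80),                           # 2^6 + 2^4
    ])
    def test_submodel_counts(self, terms, expected):
        specs = enumerate_submodels(ModelSpec(terms))
        assert len(specs) == expected
        assert len({s.fixed_terms for s in specs}) == expected  # all distinct
        assert any(s.fixed_terms == () for s in specs)          # intercept-only

    def test_marginality_enforced_everywhere(self):
        specs = enumerate_submodels(ModelSpec(("spawning", "mobility", "body_size",
                                               _INTERACTION)))
        for s in specs:
            if _INTERACTION in s.fixed_terms:
                assert "spawning" in s.fixed_terms and "mobility" in s.fixed_terms
        with pytest.raises(ValueError):
            ModelSpec(("spawning", _INTERACTION))


class TestAkaikeWeights:
    def test_single_model(self):
        np.testing.assert_allclose(akaike_weights([123.4]), [1.0])

    def test_delta_two_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-4)
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_equal_aicc_symmetry(self):
        np.testing.assert_allclose(akaike_weights([50.0] * 5), [0.2] * 5)

    def test_shift_invariance(self):
        a = np.array([10.0, 12.5, 19.0])
        np.testing.assert_allclose(akaike_weights(a), akaike_weights(a + 1234.5))

    def test_all_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([np.inf, np.nan])


def _fake_fit(terms, names, params, ses, aicc, n=1000):
    """FittedModel with a prescribed AICc, for averaging arithmetic tests."""
    k = len(params) + 1
    loglik = -(aicc - 2 * k - 2 * k * (k + 1) / (n - k - 1)) / 2
    res = lmm.MixedLMResult(
        params=np.asarray(params, float), bse=np.asarray(ses, float),
        names=list(names), sigma2=1.0, vc={}, theta=np.empty(0),
        loglik=loglik, nobs=n, n_fixed=len(params), n_vc=0, converged=True,
    )
    return FittedModel(ModelSpec(terms), res)


class TestModelAverage:
    def test_single_model_is_identity(self):
        f = _fake_fit(("body_size",), ["intercept", "body_size"], [0.3, 1.2],
                      [0.1, 0.2], aicc=100.0)
        avg = model_average([f], weight_floor=0.0)
        assert avg.model_set_size == 1
        assert avg.table.loc["body_size", "estimate"] == pytest.approx(1.2)
        assert avg.table.loc["body_size", "se"] == pytest.approx(0.2)

    def test_two_equal_weight_models_halve_absent_coefficient(self):
        # hand-computed: term present in one of two equal-weight models with
        # value 2 -> full average 1, conditional average 2
        f1 = _fake_fit(("body_size",), ["intercept", "body_size"], [0.0, 2.0],
                       [0.1, 0.4], aicc=100.0)
        f2 = _fake_fit((), ["intercept"], [0.0], [0.1], aicc=100.0)
        avg = model_average([f1, f2], weight_floor=0.0)
        assert avg.table.loc["body_size", "estimate"] == pytest.approx(1.0)
        assert avg.table.loc["body_size", "estimate_cond"] == pytest.approx(2.0)
        # unconditional SE: sqrt(.5*(0.4^2 + 1) + .5*(0 + 1))
        assert avg.table.loc["body_size", "se"] == pytest.approx(
            np.sqrt(0.5 * (0.16 + 1.0) + 0.5 * 1.0)
        )
        assert avg.table.loc["body_size", "weight"] == pytest.approx(0.5)

    def test_weight_floor_drops_implausible_models(self):
        f1 = _fake_fit(("body_size",), ["intercept", "body_size"], [0.0, 2.0],
                       [0.1, 0.4], aicc=100.0)
        f2 = _fake_fit((), ["intercept"], [0.0], [0.1], aicc=200.0)  # weight ~0
        avg = model_average([f1, f2], weight_floor=0.001)
        assert avg.model_set_size == 1
        assert avg.table.loc["body_size", "estimate"] == pytest.approx(2.0)

    def test_weights_sum_to_one(self):
        fits = [_fake_fit((), ["intercept"], [0.0], [0.1], aicc=100.0 + d)
                for d in (0.0, 1.0, 3.0)]
        avg = model_average(fits, weight_floor=0.0)
        assert avg.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_converged_fit_rejected(self):
        f = _fake_fit((), ["intercept"], [0.0], [0.1], aicc=100.0)
        f.result.converged = False
        with pytest.raises(ValueError):
            model_average([f])


class TestFullAnalysis:
    def test_recovers_strong_effects(self, pool, ranges):
        res = rr.full_analysis(pool, ranges, d_ref_km=6000.0)
        t = res.effects.table
        assert res.n_models == 40
        assert res.n_unconverged == 0
        assert t.loc["spawning_pelagic", "estimate"] > 0
        assert t.loc["spawning_pelagic", "p"] < 0.05
        assert t.loc["body_size", "p"] < 0.05
        assert t.loc["circadian_nocturnal", "estimate"] < 0
        assert res.vif.max() < 2.5

    def test_subset_restriction(self, species_focal, ranges):
        res = rr.full_analysis(species_focal, ranges, subset_col="in_focal_subset",
                               d_ref_km=6000.0)
        assert res.n_obs == 148

    def test_pld_inclusion_requires_values(self, pool, ranges):
        with pytest.raises(ValueError):
            rr.full_analysis(pool, ranges, include_pld=True, d_ref_km=6000.0)

    def test_pld_adds_submodels(self, pool, ranges):
        # moderate bias keeps enough spawning/mobility contrast for the
        # interaction to stay estimable: 2^6 + 2^4 candidate models
        flagged = rr.assign_focal_subset(pool, rr.default_bias_config(), seed=21)
        res = rr.full_analysis(flagged, ranges, include_pld=True,
                               subset_col="in_focal_subset", d_ref_km=6000.0)
        assert res.n_models == 80
        assert "pld" in res.effects.table.index

    def test_interaction_dropped_when_inestimable(self, species_focal, ranges):
        # in the severely biased focal subset virtually every mobile species
        # is pelagic; the interaction columns are collinear and are dropped
        res = rr.full_analysis(species_focal, ranges, subset_col="in_focal_subset",
                               d_ref_km=6000.0)
        assert res.n_models in (32, 40)
        if res.n_models == 32:
            assert "spawning_pelagic:mobility_high" not in res.effects.table.index
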