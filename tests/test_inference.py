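import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gardenset as gs
from gardenset import inference as inf
from gardenset.errors import ConfigurationError, ValidationError


def _recovery_frame(seed, beta=None, sigma_garden=0.3, n_gardens=30, plants=10):
    beta = beta or gs.EffectSizes(b0=0.0, b_rich=0.1, b_imp=-0.1, b_rich_x_imp=0.15,
                                  b_temp=-0.05, b_size=0.05, b_year=0, b_group=0)
    cfg = gs.SimulationConfig(
        n_gardens=n_gardens, plants_per_garden=plants, beta=beta,
        sigma_garden=sigma_garden, group_mix=1.0, seed=seed,
    )
    study = gs.simulate_study(cfg, include_sheets=False)
    df = study.truth.rename(columns={"true_fruit_set_pct": "fruit_set_pct"})
    df = gs.build_model_frame(df, study.gardens)
    df, _ = inf.scale_predictors(df)
    return df


class TestScaling:
    def test_scaled_columns_have_mean_zero_sd_one(self):
        df = _recovery_frame(seed=1)
        for col in ("z_rich", "z_imp", "z_temp", "z_size"):
            assert df[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert df[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"bee_richness": x})
        out, scaling = inf.scale_predictors(df, ["bee_richness"])
        assert np.allclose(out["z_rich"], x, atol=1e-12)
        assert scaling.loc[0, "sd"] == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"bee_richness": [5.0] * 10})
        with pytest.raises(ValidationError, match="zero SD"):
            inf.scale_predictors(df, ["bee_richness"])


class TestModelSpecGuardrails:
    def test_both_bee_metrics_rejected(self):
        with pytest.raises(ConfigurationError, match="never included simultaneously"):
            inf.ModelSpec(bee_metric=["richness", "abundance"])

    def test_two_interactions_rejected(self):
        with pytest.raises(ConfigurationError, match="one interaction"):
            inf.ModelSpec(interaction_with=["imperviousness", "temperature"])

    def test_unknown_names_rejected(self):
        with pytest.raises(ConfigurationError):
            inf.ModelSpec(bee_metric="shannon")

    def test_formulas(self):
        assert inf.ModelSpec().formula.startswith("fruit_set_pct ~ z_rich * z_imp")
        spec = inf.ModelSpec(bee_metric="abundance", interaction_with="temperature")
        assert "z_abund * z_temp" in spec.formula and spec.structure == "II"


class TestMixedModel:
    def test_matches_ols_when_no_garden_variance(self):
        # garden-level predictors and balanced groups: with sigma_garden = 0
        # the mixed-model fixed effects collapse to the OLS solution
        import statsmodels.formula.api as smf

        df = _recovery_frame(seed=3, sigma_garden=0.0)
        spec = inf.ModelSpec()
        fit = inf.fit_lmm(df, spec)
        ols = smf.ols(spec.formula, df).fit()
        mixed = fit.coefficients.set_index("term")["estimate"]
        for term in ols.params.index:
            assert mixed[term] == pytest.approx(ols.params[term], abs=0.05)

    def test_r2_ordering_and_diagnostics_present(self):
        fit = inf.fit_lmm(_recovery_frame(seed=4), inf.ModelSpec())
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
        assert set(fit.diagnostics) == {"shapiro_p", "max_vif", "std_resid_min", "std_resid_max"}
        assert np.isfinite(fit.diagnostics["max_vif"])
        assert fit.n_obs == 300 and fit.n_gardens == 30

    def test_needs_two_gardens(self):
        df = _recovery_frame(seed=5)
        with pytest.raises(ValidationError, match="two gardens"):
            inf.fit_lmm(df[df["garden_id"] == "G01"], inf.ModelSpec())


class TestAnova:
    def test_hand_computed_f_statistic(self):
        # groups {1,2,3} and {4,5,6}: SSB=13.5, MSW=1 -> F=13.5 on (1,4) df
        df = pd.DataFrame(
            {"fruit_set_pct": [1, 2, 3, 4, 5, 6],
             "participation_type": ["a"] * 3 + ["b"] * 3}
        )
        res = inf.anova_participation(df)
        assert res.f_statistic == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p_value == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        values = np.tile([50.0, 55.0, 60.0, 52.0, 58.0], 4) + rng.normal(0, 1e-6, 20)
        df = pd.DataFrame(
            {"fruit_set_pct": values,
             "participation_type": np.repeat(list("abcd"), 5)}
        )
        res = inf.anova_participation(df)
        assert res.p_value > 0.9
        assert res.tukey is None and res.letters is None

    def test_letters_match_tukey_pairs(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "fruit_set_pct": np.concatenate(
                    [rng.normal(mu, 3, 12) for mu in (40, 42, 41, 70)]
                ),
                "participation_type": np.repeat(
                    ["short-low", "short-high", "long-low", "long-high"], 12
                ),
            }
        )
        res = inf.anova_participation(df)
        assert res.p_value < 0.05 and res.letters is not None
        for _, row in res.tukey.iterrows():
            a, b = str(row["group1"]), str(row["group2"])
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share == (float(row["p-adj"]) >= 0.05)

    def test_once_excluded(self):
        df = pd.DataFrame(
            {"fruit_set_pct": [1, 2, 3, 4, 5, 6, 99],
             "participation_type": ["a"] * 3 + ["b"] * 3 + ["once"]}
        )
        assert inf.anova_participation(df).f_statistic == pytest.approx(13.5)


class TestFisher:
    def test_identical_rows_give_p_one(self):
        table = np.array([[5, 10], [5, 10], [5, 10], [5, 10]])
        assert inf.fisher_exact_rx2(table) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[3, 9], [7, 2]], [[0, 5], [5, 0]], [[2, 3], [4, 1]], [[8, 1], [2, 7]],
         [[12, 0], [0, 12]]],
    )
    def test_2x2_matches_hypergeometric_oracle(self, table):
        expected = stats.fisher_exact(table).pvalue
        assert inf.fisher_exact_rx2(table) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "table,expected",
        [
            # reference p-values computed with R 4.3.3 fisher.test
            ([[6, 15], [3, 13], [12, 38], [10, 48]], 0.65651207),
            ([[9, 12], [2, 14], [11, 39], [5, 53]], 0.006055035496),
        ],
    )
    def test_4x2_matches_r_reference(self, table, expected):
        assert inf.fisher_exact_rx2(table) == pytest.approx(expected, rel=1e-8)

    def test_pairwise_gated_on_omnibus(self):
        flat = pd.DataFrame([[5, 10]] * 4, index=list("abcd"))
        skewed = pd.DataFrame([[18, 2], [2, 18], [10, 10], [9, 11]], index=list("abcd"))
        results = inf.fisher_challenges({"flat": flat, "skewed": skewed})
        assert results["flat"].pairwise is None
        pw = results["skewed"].pairwise
        assert pw is not None and len(pw) == 6
        assert (pw["p_holm"] >= pw["p_raw"] - 1e-12).all()


class TestSpearman:
    def _gardens(self, richness, abundance):
        return pd.DataFrame({"bee_richness": richness, "bee_abundance": abundance})

    def test_monotone_pair(self):
        rho, _ = inf.spearman_rich_abund(self._gardens([1, 2, 3, 4], [10, 20, 30, 40]))
        assert rho == pytest.approx(1.0)

    def test_reversed_pair(self):
        rho, _ = inf.spearman_rich_abund(self._gardens([1, 2, 3, 4], [40, 30, 20, 10]))
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self):
        rich = [3, 3, 5, 7, 7, 9]
        abund = [10, 14, 14, 30, 22, 40]
        rho, _ = inf.spearman_rich_abund(self._gardens(rich, abund))
        oracle = stats.pearsonr(stats.rankdata(rich), stats.rankdata(abund))[0]
        assert rho == pytest.approx(oracle, rel=1e-12)
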