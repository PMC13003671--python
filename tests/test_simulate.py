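import numpy as np
import pytest
from scipy.special import expit

import gardenset as gs
from gardenset.errors import ConfigurationError
from gardenset.fruitset import apply_quality_criteria
from gardenset.sheets import series_to_frame
from gardenset.simulate import ERROR_TYPES, inject_errors


def _null_beta(b0=0.0):
    return gs.EffectSizes(b0=b0, b_rich=0, b_imp=0, b_rich_x_imp=0,
                          b_temp=0, b_size=0, b_year=0, b_group=0)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = gs.SimulationConfig(n_gardens=5, plants_per_garden=4, seed=42)
        a = gs.simulate_study(cfg)
        b = gs.simulate_study(cfg)
        assert series_to_frame(a.sheets).to_csv() == series_to_frame(b.sheets).to_csv()
        assert a.truth.equals(b.truth)
        assert a.gardens == b.gardens

    def test_truth_unchanged_by_skipping_sheets(self):
        cfg = gs.SimulationConfig(n_gardens=4, plants_per_garden=3, seed=8)
        with_sheets = gs.simulate_study(cfg, include_sheets=True)
        without = gs.simulate_study(cfg, include_sheets=False)
        assert with_sheets.truth.equals(without.truth)


class TestGroundTruth:
    def test_forced_zero_conversion(self):
        cfg = gs.SimulationConfig(
            n_gardens=4, plants_per_garden=5, beta=_null_beta(b0=-50.0), seed=1
        )
        study = gs.simulate_study(cfg, include_sheets=False)
        assert (study.truth["true_fruits_set"] == 0).all()

    def test_mean_conversion_matches_intercept(self):
        # intercept-only model: pooled conversion rate ~ expit(b0)
        b0 = -0.4
        cfg = gs.SimulationConfig(
            n_gardens=100, plants_per_garden=5, beta=_null_beta(b0=b0),
            sigma_garden=0.0, seed=2,
        )
        study = gs.simulate_study(cfg, include_sheets=False)
        flowers = study.truth["true_flowers_bloomed"].sum()
        fruits = study.truth["true_fruits_set"].sum()
        p = expit(b0)
        se = np.sqrt(p * (1 - p) / flowers)
        assert abs(fruits / flowers - p) < 3 * se

    def test_truth_internal_consistency(self):
        study = gs.simulate_study(
            gs.SimulationConfig(n_gardens=5, plants_per_garden=4, seed=3),
            include_sheets=False,
        )
        t = study.truth
        ok = t["true_flowers_bloomed"] > 0
        expected = 100.0 * t.loc[ok, "true_fruits_set"] / t.loc[ok, "true_flowers_bloomed"]
        assert np.allclose(t.loc[ok, "true_fruit_set_pct"], expected)
        assert t["true_fruit_set_pct"].dropna().between(0, 100).all()

    def test_interaction_effect_visible_in_truth(self):
        # with b_rich_x_imp > 0 the product of standardized richness and
        # imperviousness correlates positively with plant fruit set
        beta = gs.EffectSizes(b0=0.0, b_rich=0, b_imp=0, b_rich_x_imp=0.5,
                              b_temp=0, b_size=0, b_year=0, b_group=0)
        cfg = gs.SimulationConfig(
            n_gardens=120, plants_per_garden=5, beta=beta, sigma_garden=0.0, seed=4
        )
        study = gs.simulate_study(cfg, include_sheets=False)
        gdf = gs.sheets.gardens_to_frame(study.gardens)
        z = lambda x: (x - x.mean()) / x.std()
        gdf["zz"] = z(gdf["bee_richness"]) * z(gdf["imperviousness_pct"])
        df = study.truth.merge(gdf[["garden_id", "zz"]], on="garden_id")
        corr = np.corrcoef(df["zz"], df["true_fruit_set_pct"])[0, 1]
        assert corr > 0.2

    def test_rank_correlation_of_richness_and_abundance(self):
        cfg = gs.SimulationConfig(n_gardens=400, plants_per_garden=1, seed=5)
        study = gs.simulate_study(cfg, include_sheets=False)
        rho, _ = gs.spearman_rich_abund(study.gardens)
        assert rho == pytest.approx(0.52, abs=0.12)
        assert all(g.bee_richness <= g.bee_abundance for g in study.gardens)


class TestErrorInjection:
    def test_zero_rates_identity(self):
        study = gs.simulate_study(
            gs.SimulationConfig(n_gardens=4, plants_per_garden=3, seed=6,
                                error_rates={t: 0.0 for t in ERROR_TYPES})
        )
        out, log = inject_errors(study.sheets, {t: 0.0 for t in ERROR_TYPES}, seed=1)
        assert out == study.sheets
        assert log == {}

    def test_forced_initial_fruit_fails_qc3(self):
        # daily schedule from day 0: without injection no series starts
        # with a fruit, so criterion 3 failures are exactly the injected ones
        cfg = gs.SimulationConfig(n_gardens=5, plants_per_garden=2, seed=7,
                                  error_rates={t: 0.0 for t in ERROR_TYPES})
        study = gs.simulate_study(cfg, schedule_override=gs.daily_schedule(cfg))
        ten = study.sheets[:10]
        out, log = inject_errors(ten, {"initial_fruit": 1.0}, seed=1)
        assert set(log.values()) == {"initial_fruit"}
        reports = apply_quality_criteria(out, min_plants_per_garden_year=1)
        assert all(r.first_failed_criterion == 3 for r in reports)

    def test_rng_replay_reproduces_selection(self):
        study = gs.simulate_study(
            gs.SimulationConfig(n_gardens=20, plants_per_garden=10, seed=8)
        )
        rates = {t: 0.1 for t in ERROR_TYPES}
        out, log = inject_errors(study.sheets, rates, seed=99)
        # replay the documented RNG stream independently
        rng = np.random.default_rng([99, 777_000_001])
        expected = {}
        for s in study.sheets:
            draws = rng.random(len(ERROR_TYPES))
            for i, etype in enumerate(ERROR_TYPES):
                if draws[i] < rates[etype]:
                    expected[s.plant_id] = etype
                    break
        assert log == expected
        assert len(log) > 0

    def test_each_corruption_trips_its_criterion(self):
        cfg = gs.SimulationConfig(n_gardens=4, plants_per_garden=2, seed=9,
                                  error_rates={t: 0.0 for t in ERROR_TYPES})
        study = gs.simulate_study(cfg, schedule_override=gs.daily_schedule(cfg))
        targets = {"unknown_crop": 1, "too_few_visits": 2, "initial_fruit": 3, "implausible": 4}
        for etype, criterion in targets.items():
            out, log = inject_errors(study.sheets[:4], {etype: 1.0}, seed=2)
            reports = apply_quality_criteria(out, min_plants_per_garden_year=1)
            assert {r.first_failed_criterion for r in reports} == {criterion}, etype


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"group_mix": 1.5}, "group_mix"),
            ({"n_gardens": 0}, "n_gardens"),
            ({"loss_rate": -0.1}, "loss_rate"),
            ({"flowering_days": 200, "season_days": 100}, "flowering_days"),
            ({"error_rates": {"bogus": 0.1}}, "bogus"),
            ({"error_rates": {"implausible": 1.2}}, "implausible"),
            ({"type_mix": {"long-high": 0.5}}, "type_mix"),
        ],
    )
    def test_invalid_values_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            gs.SimulationConfig(**kwargs)
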