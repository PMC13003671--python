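"""Validation experiments against simulator ground truth.

These are the package's own correctness studies: ledger exactness under
ideal observation, the telescoping fruit identity, a hand-worked ledger
example, planted quality-control violations, typology boundary behaviour,
parameter recovery and type-I error of the mixed model, and the direction
of the observer bias induced by sparse visit schedules when ripe fruits can
disappear between visits.  Both the test suite and the acceptance script
run these functions; all randomness flows from an explicit seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import inference as inf
from . import participation as part
from .errors import MissingCountError, UndefinedFruitSetError
from .fruitset import apply_quality_criteria, compute_fruit_set, exclusion_table
from .sheets import ObservationRecord, ObservationSeries
from .simulate import (
    EffectSizes,
    SimulationConfig,
    _draw_gardens,
    _standardize_garden,
    conversion_probability,
    daily_schedule,
    simulate_study,
)

#: Effect sizes used by the recovery experiment: a moderate positive
#: richness x imperviousness interaction around a 50% baseline fruit set.
RECOVERY_BETA = EffectSizes(
    b0=0.0, b_rich=0.10, b_imp=-0.10, b_rich_x_imp=0.15,
    b_temp=-0.05, b_size=0.05, b_year=0.0, b_group=0.0,
)

NULL_BETA = EffectSizes(
    b0=0.0, b_rich=0.0, b_imp=0.0, b_rich_x_imp=0.0,
    b_temp=0.0, b_size=0.0, b_year=0.0, b_group=0.0,
)

_NO_ERRORS = {
    "unknown_crop": 0.0,
    "too_few_visits": 0.0,
    "initial_fruit": 0.0,
    "implausible": 0.0,
}


def ledger_exactness(seed: int, n_gardens: int = 30, plants_per_garden: int = 5) -> dict:
    """Reconstruct every plant under daily visits, zero fruit loss and no
    injected errors, and compare against event-level truth.

    Under these conditions every stage transition is visible at some visit,
    so both totals must match the truth exactly for every plant.
    """
    cfg = SimulationConfig(
        n_gardens=n_gardens,
        plants_per_garden=plants_per_garden,
        loss_rate=0.0,
        error_rates=_NO_ERRORS,
        seed=seed,
    )
    study = simulate_study(cfg, schedule_override=daily_schedule(cfg))
    truth = study.truth.set_index("plant_id")
    n_plants = n_exact = 0
    for s in study.sheets:
        t_flowers = int(truth.loc[s.plant_id, "true_flowers_bloomed"])
        t_fruits = int(truth.loc[s.plant_id, "true_fruits_set"])
        n_plants += 1
        try:
            res = compute_fruit_set(s)
        except UndefinedFruitSetError:
            n_exact += t_flowers == 0 and t_fruits == 0
            continue
        n_exact += res.total_flowers == t_flowers and res.total_fruits == t_fruits
    return {
        "n_plants": n_plants,
        "n_exact": n_exact,
        "exact_fraction_pct": 100.0 * n_exact / n_plants,
    }


def telescoping_check(seed: int, n_series: int = 500) -> dict:
    """Randomized series with complete harvest reporting and zero loss:
    the fruit total must equal R_T + sum(H) - R_0 for every one."""
    rng = np.random.default_rng(seed)
    import datetime as dt

    base = dt.date(2021, 6, 1)
    violations = 0
    for k in range(n_series):
        n = int(rng.integers(2, 9))
        R, H = [0], [0]
        for _ in range(1, n):
            stock = R[-1] + int(rng.integers(0, 6))
            h = int(rng.integers(0, stock + 1))
            H.append(h)
            R.append(stock - h)
        records = [
            ObservationRecord(
                visit_date=base + dt.timedelta(days=3 * i),
                open_flowers=int(rng.integers(0, 6)),
                faded_flowers=int(rng.integers(0, 6)),
                fruits_on_plant=R[i],
                fruits_harvested=H[i],
            )
            for i in range(n)
        ]
        series = ObservationSeries(
            plant_id=f"T{k}", garden_id="G", year=2021, crop="cucumber",
            records=records,
        )
        from .fruitset import total_fruits

        total, _ = total_fruits(series)
        if total != R[-1] + sum(H) - R[0]:
            violations += 1
    return {"n_series": n_series, "violations": violations}


def worked_example() -> dict:
    """The five-visit ledger example worked through by hand."""
    import datetime as dt

    base = dt.date(2021, 6, 1)
    O = (2, 3, 1, 0, 0)
    F = (0, 1, 2, 1, 0)
    R = (0, 0, 2, 2, 1)
    H = (0, 0, 0, 1, 1)
    series = ObservationSeries(
        plant_id="worked", garden_id="G", year=2021, crop="cucumber",
        records=[
            ObservationRecord(
                visit_date=base + dt.timedelta(days=3 * i),
                open_flowers=O[i], faded_flowers=F[i],
                fruits_on_plant=R[i], fruits_harvested=H[i],
            )
            for i in range(5)
        ],
    )
    res = compute_fruit_set(series)
    return {
        "total_fruits": res.total_fruits,
        "total_flowers": res.total_flowers,
        "fruit_set_pct": res.fruit_set_pct,
    }


def planted_qc_study() -> dict:
    """A 20-series study with planted violations and its QC outcome.

    Planted: 2 unlisted crops, 3 too-short series, 4 with an initial fruit,
    3 with a negative-count typo, and 8 clean series of which 2 sit in an
    under-replicated garden-year.
    """
    import datetime as dt

    base = dt.date(2021, 6, 1)

    def series(pid, O, F, R, H, crop="cucumber", garden="GA"):
        return ObservationSeries(
            plant_id=pid, garden_id=garden, year=2021, crop=crop, crop_raw=crop,
            records=[
                ObservationRecord(
                    visit_date=base + dt.timedelta(days=3 * i),
                    open_flowers=O[i], faded_flowers=F[i],
                    fruits_on_plant=R[i], fruits_harvested=H[i],
                )
                for i in range(len(O))
            ],
        )

    clean = dict(O=(3, 2, 1, 0), F=(0, 2, 3, 4), R=(0, 1, 2, 2), H=(0, 0, 0, 1))
    all_series = [
        series("c1-a", (1, 1, 0), (0, 0, 1), (0, 0, 0), (0, 0, 0), crop="other"),
        series("c1-b", (1, 1), (0, 0), (0, 0), (0, 0), crop="other"),
    ]
    all_series += [
        series(f"c2-{i}", (2, 1), (0, 1), (0, 0), (0, 0)) for i in range(3)
    ]
    all_series += [
        series(f"c3-{i}", (2, 1, 0), (0, 1, 2), (1, 1, 1), (0, 0, 0)) for i in range(4)
    ]
    all_series += [
        series(f"c4-{i}", (2, -3, 0), (0, 1, 2), (0, 0, 1), (0, 0, 0)) for i in range(3)
    ]
    all_series += [series(f"ok-{i}", **clean) for i in range(6)]
    all_series += [series(f"gb-{i}", **clean, garden="GB") for i in range(2)]

    reports = apply_quality_criteria(all_series)
    table = exclusion_table(reports).set_index("criterion")["excluded"]
    planted = {1: 2, 2: 3, 3: 4, 4: 3, 5: 2}
    detected = {c: int(table.loc[c]) for c in planted}
    return {
        "planted": planted,
        "detected": detected,
        "all_match": planted == detected,
        "n_passed": int(sum(r.passed for r in reports)),
    }


def typology_boundaries() -> dict:
    """Boundary behaviour of the participation typology and break flag."""
    import datetime as dt

    base = dt.date(2021, 6, 1)

    def on_days(days):
        return ObservationSeries(
            plant_id="x", garden_id="G", year=2021, crop="cucumber",
            records=[
                ObservationRecord(
                    visit_date=base + dt.timedelta(days=d),
                    open_flowers=1, faded_flowers=0,
                    fruits_on_plant=0, fruits_harvested=0,
                )
                for d in days
            ],
        )

    d56 = part.participation_profile(on_days([0, 56]))
    f4 = part.participation_profile(on_days([0, 5, 10, 15, 20, 25, 30, 33, 36, 40]))
    return {
        "duration_56_is_long": d56.type.startswith("long"),
        "frequency_4_is_high": f4.frequency == 4.0 and f4.type.endswith("high"),
        "gap_10_no_break": not part.detect_long_break(on_days([0, 10, 20])),
        "gap_11_break": part.detect_long_break(on_days([0, 11, 15])),
    }


def population_interaction_effect(
    beta: EffectSizes,
    sigma_garden: float,
    n_gardens: int = 20000,
    seed: int = 12345,
) -> float:
    """Percent-scale population value of the interaction coefficient.

    The generative model is logistic in the covariates while the fitted
    model is linear on the fruit-set percentage, so the estimand of the
    linear mixed model is the population least-squares projection of the
    expected fruit set (100p) onto the model's design.  This computes that
    projection's interaction coefficient by Monte Carlo over the covariate
    and random-intercept distributions.
    """
    cfg = SimulationConfig(
        n_gardens=n_gardens, plants_per_garden=1, beta=beta,
        sigma_garden=sigma_garden, seed=seed,
    )
    gardens, intercepts = _draw_gardens(cfg)
    z = np.array(
        [
            [
                _standardize_garden(g, cfg.covariates)[k]
                for k in ("z_rich", "z_imp", "z_temp", "z_size")
            ]
            for g in gardens
        ]
    )
    y = 100.0 * np.array(
        [
            conversion_probability(cfg, g, intercepts[i], "Cucurbitaceae")
            for i, g in enumerate(gardens)
        ]
    )
    year = np.array([g.year == 2021 for g in gardens], dtype=float)
    X = np.column_stack(
        [np.ones(len(y)), z[:, 0], z[:, 1], z[:, 0] * z[:, 1], z[:, 2], z[:, 3], year]
    )
    coef = np.linalg.lstsq(X, y, rcond=None)[0]
    return float(coef[3])


def _fit_interaction(study) -> tuple[float, float, float]:
    df = study.truth.rename(columns={"true_fruit_set_pct": "fruit_set_pct"})
    df = inf.build_model_frame(df, study.gardens)
    df, _ = inf.scale_predictors(df)
    fit = inf.fit_lmm(df, inf.ModelSpec())
    row = fit.coefficients.set_index("term").loc["z_rich:z_imp"]
    return float(row["estimate"]), float(row["se"]), float(row["p"])


def interaction_recovery(
    seed: int,
    n_replicates: int = 100,
    n_gardens: int = 30,
    plants_per_garden: int = 10,
    sigma_garden: float = 0.3,
) -> dict:
    """Coverage of the 95% interval for the interaction across replicates."""
    true_effect = population_interaction_effect(
        RECOVERY_BETA, sigma_garden, seed=seed + 900_000
    )
    covered = 0
    estimates = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_gardens=n_gardens, plants_per_garden=plants_per_garden,
            beta=RECOVERY_BETA, sigma_garden=sigma_garden, group_mix=1.0,
            seed=seed + rep,
        )
        study = simulate_study(cfg, include_sheets=False)
        est, se, _ = _fit_interaction(study)
        estimates.append(est)
        if est - 1.96 * se <= true_effect <= est + 1.96 * se:
            covered += 1
    return {
        "n_replicates": n_replicates,
        "true_effect": true_effect,
        "mean_estimate": float(np.mean(estimates)),
        "coverage_pct": 100.0 * covered / n_replicates,
    }


def null_type1_rate(
    seed: int,
    n_replicates: int = 200,
    n_gardens: int = 40,
    plants_per_garden: int = 10,
) -> dict:
    """Rejection rate of the interaction at alpha = 0.05 when no effect and
    no garden variance exist (400 plants per replicate)."""
    rejections = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_gardens=n_gardens, plants_per_garden=plants_per_garden,
            beta=NULL_BETA, sigma_garden=0.0, group_mix=1.0,
            seed=seed + 500_000 + rep,
        )
        study = simulate_study(cfg, include_sheets=False)
        _, _, p = _fit_interaction(study)
        rejections += p < 0.05
    return {
        "n_replicates": n_replicates,
        "type1_rate": rejections / n_replicates,
    }


def observer_bias_experiment(
    seed: int,
    n_replicates: int = 50,
    n_gardens: int = 16,
    plants_per_garden: int = 10,
    loss_rate: float = 0.05,
) -> dict:
    """Sparse schedules under fruit loss: long/low contributions should
    reconstruct a lower mean fruit set than long/high ones.

    Every replicate simulates one study whose plants are split between the
    two long-duration schedule types; the per-replicate difference in mean
    reconstructed fruit set is tested one-sided across replicates.  The
    bias only arises from fruits that ripen and disappear inside a single
    inter-visit gap (a fruit seen once is counted forever), so it is a
    small per-plant effect; the per-replicate study is sized at 160 plants
    to give the 50-replicate test adequate power.
    """
    diffs = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_gardens=n_gardens, plants_per_garden=plants_per_garden,
            loss_rate=loss_rate, error_rates=_NO_ERRORS,
            type_mix={"long-low": 0.5, "long-high": 0.5},
            seed=seed + 300_000 + rep,
        )
        study = simulate_study(cfg)
        by_type: dict[str, list[float]] = {"long-low": [], "long-high": []}
        for s in study.sheets:
            try:
                res = compute_fruit_set(s)
            except (UndefinedFruitSetError, MissingCountError):
                continue
            ptype = part.participation_profile(s).type
            if ptype in by_type:
                by_type[ptype].append(res.fruit_set_pct)
        if by_type["long-low"] and by_type["long-high"]:
            diffs.append(np.mean(by_type["long-low"]) - np.mean(by_type["long-high"]))
    t = stats.ttest_1samp(diffs, 0.0, alternative="less")
    return {
        "n_replicates": len(diffs),
        "mean_diff_longlow_minus_longhigh": float(np.mean(diffs)),
        "p_one_sided": float(t.pvalue),
    }
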