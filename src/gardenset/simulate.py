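"""Synthetic garden seasons with known ground truth.

The generator builds a whole citizen-science study from the bottom up:

* gardens with realized covariates (imperviousness, growing-season
  temperature, size, year, and bee richness/abundance drawn from a Gaussian
  copula so their rank correlation matches the study-wide value of about
  0.52), plus a Gaussian random intercept per garden;
* plants, each with a crop, a per-flower fruit-conversion probability
  ``p = expit(linear predictor + garden intercept)`` where the linear
  predictor mirrors the richness x imperviousness interaction model fitted
  downstream;
* flower-level events: openings arrive as a homogeneous Poisson process
  over the flowering window, stay open for a (truncated) geometric number
  of days, then either convert to a fruit or fade; fruits ripen after a
  geometric lag, may be lost unobserved (theft, rot) at a per-day rate once
  ripe, and are otherwise harvested at the first visit after ripening;
* gardener visit schedules per participation type (start, duration, visit
  interval, optional multi-day breaks), two harvest-reporting conventions
  (count-first and harvest-first), occasional free-text comments, and
  labelled data-entry corruptions that trigger each quality criterion.

Ground truth (flowers bloomed, fruits set, fruit-set percentage, garden
intercepts) is recorded *before* error injection.  Every plant owns an RNG
stream derived from the master seed plus its garden and plant index, so
per-plant results are stable under reordering, and truth is unchanged by
whether observation sheets are generated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import datetime as _dt

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .sheets import (
    CROP_GROUPS,
    GardenContext,
    ObservationRecord,
    ObservationSeries,
)

CUCURBIT_CROPS = ("cucumber", "zucchini", "pumpkin")
SELFING_CROPS = ("tomato", "pepper", "pepperoni", "chili", "strawberry")

#: Calendar anchor: simulation day 0 maps to this date (start of the
#: growing-season observation window).
SEASON_START = _dt.date(2021, 5, 15)

ERROR_TYPES = ("unknown_crop", "too_few_visits", "initial_fruit", "implausible")

_COMMENT_PHRASES = {
    "plant_health": "Plant looks weakened, mildew on the leaves.",
    "plant_death": "Plant is dead.",
    "harvest_loss": "1 rotten fruit removed",
    "protocol": "Not sure about the last measurement.",
}


@dataclass(frozen=True)
class EffectSizes:
    """Coefficients on the logit of per-flower conversion probability.

    All continuous covariates enter standardized (theoretical moments of
    their generating distributions), so coefficients are per-SD effects on
    the logit scale.  ``b_group`` is the offset for the self-pollinating
    group (tomato/pepper/pepperoni/chili plus strawberry) relative to the
    cucurbits; ``b_year`` is the offset for the second study year.
    """

    b0: float = -0.59
    b_rich: float = 0.10
    b_imp: float = -0.15
    b_rich_x_imp: float = 0.15
    b_temp: float = -0.05
    b_size: float = 0.05
    b_year: float = 0.0
    b_group: float = 0.93


@dataclass(frozen=True)
class ScheduleSpec:
    """Visit-schedule recipe for one participation type.

    Days are integers from the start of the season; ``interval_days`` is an
    inclusive range sampled per gap; with probability ``break_probability``
    one break of ``break_length_days`` replaces a regular gap.
    """

    start_window: tuple[int, int]
    duration_days: tuple[int, int]
    interval_days: tuple[int, int]
    break_probability: float = 0.0
    break_length_days: tuple[int, int] = (11, 15)


#: Default schedules per participation type.  Duration/interval ranges are
#: anchored to the per-type mean durations and frequencies observed in the
#: study (short-low 41 d at 5.8 d/measurement, short-high 36 d at 3.5,
#: long-low 81 d at 6.0, long-high 92 d at 3.7), with breaks of more than
#: ten days concentrated in the long/low type.  Start windows are tight:
#: gardeners typically began observing within days of first bloom, and
#: later starts make the series fail the no-initial-fruit criterion.
DEFAULT_SCHEDULES: dict[str, ScheduleSpec] = {
    "short-low": ScheduleSpec((0, 3), (25, 54), (5, 7), 0.10),
    "short-high": ScheduleSpec((0, 3), (25, 54), (3, 4), 0.05),
    "long-low": ScheduleSpec((0, 3), (60, 100), (5, 7), 0.65, (11, 15)),
    "long-high": ScheduleSpec((0, 3), (70, 110), (3, 4), 0.10, (11, 13)),
}

#: Share of contributions per type, anchored to the observed split
#: (5 single-visit series of 150; 21/16/50/58 of the 145 typed series).
DEFAULT_TYPE_MIX: dict[str, float] = {
    "once": 0.033,
    "short-low": 0.14,
    "short-high": 0.107,
    "long-low": 0.333,
    "long-high": 0.387,
}


@dataclass(frozen=True)
class CovariateRanges:
    """Generating distributions for the garden covariates.

    Imperviousness, temperature and size are uniform over the printed study
    ranges; richness is (rounded) Gaussian and abundance log-normal, linked
    through a Gaussian copula targeting the study's rank correlation.
    """

    imperviousness_pct: tuple[float, float] = (20.9, 96.2)
    mean_temp_c: tuple[float, float] = (18.4, 21.5)
    size_ha: tuple[float, float] = (0.04, 2.39)
    richness_mean: float = 25.2
    richness_sd: float = 7.5
    abundance_mean: float = 153.7
    abundance_sd: float = 122.8
    richness_abundance_rho: float = 0.52


@dataclass(frozen=True)
class SimulationConfig:
    n_gardens: int = 22
    plants_per_garden: int = 7
    group_mix: float = 0.45          # share of Cucurbitaceae-group plants
    beta: EffectSizes = field(default_factory=EffectSizes)
    sigma_garden: float = 0.3        # SD of the garden random intercept (logit)
    covariates: CovariateRanges = field(default_factory=CovariateRanges)
    season_days: int = 120           # observation horizon (days)
    flowering_days: int = 60         # openings occur in [0, flowering_days)
    flower_rate: float = 0.8         # mean openings per plant per day
    open_lifespan_days: float = 2.0  # mean days a flower stays open
    open_lifespan_max: int = 7
    faded_persistence_days: float | None = None  # None: faded flowers persist
    fruit_ripening_days: float = 8.0  # mean lag from fruit formation to ripe
    loss_rate: float = 0.01          # per-day loss probability of a ripe fruit
    type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    schedules: Mapping[str, ScheduleSpec] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES)
    )
    harvest_mode_mix: float = 0.25   # share of harvest-first reporters
    comment_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "plant_health": 0.10,
            "plant_death": 0.03,
            "harvest_loss": 0.08,
            "protocol": 0.06,
        }
    )
    #: Default data-entry error rates, anchored to the share of real
    #: contributions excluded for an unlisted crop (2/150), a too-short
    #: series (4/150) and implausible entries (10/150).  Fruits already
    #: present at the first visit arise naturally from late schedule starts,
    #: so that error type is not injected by default.
    error_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "unknown_crop": 0.013,
            "too_few_visits": 0.027,
            "initial_fruit": 0.0,
            "implausible": 0.067,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("n_gardens", self.n_gardens)
        _check_positive("plants_per_garden", self.plants_per_garden)
        _check_probability("group_mix", self.group_mix)
        _check_probability("harvest_mode_mix", self.harvest_mode_mix)
        _check_probability("loss_rate", self.loss_rate)
        if self.sigma_garden < 0:
            raise ConfigurationError("sigma_garden must be non-negative")
        _check_positive("season_days", self.season_days)
        _check_positive("flowering_days", self.flowering_days)
        if self.flowering_days > self.season_days:
            raise ConfigurationError(
                "flowering_days must not exceed season_days"
            )
        if self.flower_rate <= 0:
            raise ConfigurationError("flower_rate must be positive")
        if self.open_lifespan_days < 1:
            raise ConfigurationError("open_lifespan_days must be at least 1")
        _check_positive("open_lifespan_max", self.open_lifespan_max)
        if self.faded_persistence_days is not None and self.faded_persistence_days < 1:
            raise ConfigurationError("faded_persistence_days must be at least 1")
        if self.fruit_ripening_days < 0:
            raise ConfigurationError("fruit_ripening_days must be non-negative")
        for name, rate in {**self.error_rates}.items():
            if name not in ERROR_TYPES:
                raise ConfigurationError(f"error_rates: unknown error type {name!r}")
            _check_probability(f"error_rates[{name}]", rate)
        for name, rate in {**self.comment_rates}.items():
            _check_probability(f"comment_rates[{name}]", rate)
        total = sum(self.type_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigurationError(
                f"type_mix proportions must sum to 1 (got {total})"
            )
        for t in self.type_mix:
            if t != "once" and t not in self.schedules:
                raise ConfigurationError(f"type_mix names unscheduled type {t!r}")


def _check_positive(name: str, value) -> None:
    if value <= 0:
        raise ConfigurationError(f"{name} must be positive (got {value})")


def _check_probability(name: str, value) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1] (got {value})")


@dataclass
class SimulatedStudy:
    """A complete synthetic study: sheets, garden table and ground truth."""

    sheets: list[ObservationSeries]
    gardens: list[GardenContext]
    truth: pd.DataFrame
    corruption_log: dict[str, str] = field(default_factory=dict)
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# garden level
# ---------------------------------------------------------------------------


def _draw_gardens(config: SimulationConfig) -> tuple[list[GardenContext], np.ndarray]:
    """Realize garden covariates and random intercepts.

    Richness/abundance come from a Gaussian copula; the Pearson correlation
    of the underlying normals is 2*sin(pi*rho_s/6) so the rank correlation
    of the transformed pair targets the configured Spearman rho.
    """
    rng = np.random.default_rng([config.seed, 1_000_003])
    cr = config.covariates
    n = config.n_gardens

    r_pearson = 2.0 * np.sin(np.pi * cr.richness_abundance_rho / 6.0)
    cov = np.array([[1.0, r_pearson], [r_pearson, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    richness = np.maximum(2, np.rint(cr.richness_mean + cr.richness_sd * z[:, 0]))
    sigma2 = np.log1p((cr.abundance_sd / cr.abundance_mean) ** 2)
    sigma = np.sqrt(sigma2)
    mu = np.log(cr.abundance_mean) - sigma2 / 2.0
    abundance = np.rint(np.exp(mu + sigma * z[:, 1]))
    abundance = np.maximum(abundance, richness)  # richness <= abundance

    imp = rng.uniform(*cr.imperviousness_pct, size=n)
    temp = rng.uniform(*cr.mean_temp_c, size=n)
    size = rng.uniform(*cr.size_ha, size=n)
    years = np.where(rng.random(n) < 0.5, 2020, 2021)
    intercepts = rng.normal(0.0, config.sigma_garden, size=n)

    gardens = [
        GardenContext(
            garden_id=f"G{g + 1:02d}",
            city="Berlin" if g % 2 == 0 else "Munich",
            year=int(years[g]),
            size_ha=float(size[g]),
            imperviousness_pct=float(imp[g]),
            mean_temp_c=float(temp[g]),
            bee_richness=int(richness[g]),
            bee_abundance=int(abundance[g]),
        )
        for g in range(n)
    ]
    return gardens, intercepts


def _standardize_garden(g: GardenContext, cr: CovariateRanges) -> dict[str, float]:
    def _unif_z(x, lo, hi):
        return (x - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))

    return {
        "z_rich": (g.bee_richness - cr.richness_mean) / cr.richness_sd,
        "z_imp": _unif_z(g.imperviousness_pct, *cr.imperviousness_pct),
        "z_temp": _unif_z(g.mean_temp_c, *cr.mean_temp_c),
        "z_size": _unif_z(g.size_ha, *cr.size_ha),
    }


def conversion_probability(
    config: SimulationConfig,
    garden: GardenContext,
    garden_intercept: float,
    group: str,
) -> float:
    """Per-flower fruit-conversion probability for one plant."""
    b = config.beta
    z = _standardize_garden(garden, config.covariates)
    eta = (
        b.b0
        + b.b_rich * z["z_rich"]
        + b.b_imp * z["z_imp"]
        + b.b_rich_x_imp * z["z_rich"] * z["z_imp"]
        + b.b_temp * z["z_temp"]
        + b.b_size * z["z_size"]
        + b.b_year * (garden.year == 2021)
        + b.b_group * (group == "Solanaceae")
        + garden_intercept
    )
    return float(expit(eta))


# ---------------------------------------------------------------------------
# plant level
# ---------------------------------------------------------------------------


def _truncated_geometric(rng, mean: float, cap: int | None, size: int) -> np.ndarray:
    if mean <= 1.0:
        draws = np.ones(size, dtype=int)
    else:
        draws = rng.geometric(1.0 / mean, size=size)
    if cap is not None:
        draws = np.minimum(draws, cap)
    return draws


@dataclass
class _PlantEvents:
    """Event-level fate of every flower on one plant."""

    open_day: np.ndarray      # day the flower opened
    open_end: np.ndarray      # first day no longer open
    fade_end: np.ndarray      # first day a faded (non-converted) flower is gone
    converts: np.ndarray      # bool: developed into a fruit
    ripe_day: np.ndarray      # day the fruit becomes harvestable
    loss_day: np.ndarray      # day a ripe, unharvested fruit disappears


def _simulate_flowers(rng, config: SimulationConfig, p_convert: float) -> _PlantEvents:
    n = rng.poisson(config.flower_rate * config.flowering_days)
    open_day = rng.integers(0, config.flowering_days, size=n)
    open_len = _truncated_geometric(
        rng, config.open_lifespan_days, config.open_lifespan_max, n
    )
    open_end = open_day + open_len
    converts = rng.random(n) < p_convert
    if config.faded_persistence_days is None:
        fade_end = np.full(n, np.iinfo(np.int64).max // 2)
    else:
        fade_len = _truncated_geometric(rng, config.faded_persistence_days, None, n)
        fade_end = open_end + fade_len
    ripen = _truncated_geometric(rng, max(config.fruit_ripening_days, 1.0), None, n)
    ripe_day = open_end + ripen
    if config.loss_rate > 0:
        loss_day = ripe_day + rng.geometric(config.loss_rate, size=n)
    else:
        loss_day = np.full(n, np.iinfo(np.int64).max // 2)
    return _PlantEvents(open_day, open_end, fade_end, converts, ripe_day, loss_day)


def _draw_schedule(rng, spec: ScheduleSpec, season_days: int) -> np.ndarray:
    start = int(rng.integers(spec.start_window[0], spec.start_window[1] + 1))
    duration = int(rng.integers(spec.duration_days[0], spec.duration_days[1] + 1))
    end = start + duration
    take_break = rng.random() < spec.break_probability
    break_at = rng.uniform(0.25, 0.75) if take_break else None

    days = [start]
    while days[-1] < end:
        gap = int(rng.integers(spec.interval_days[0], spec.interval_days[1] + 1))
        if break_at is not None and days[-1] - start >= break_at * duration:
            gap = int(rng.integers(*spec.break_length_days)) + 1
            break_at = None
        days.append(days[-1] + gap)
    # final visit lands on or just past the intended end; keep it
    return np.array(days)


def daily_schedule(config: SimulationConfig) -> np.ndarray:
    """A visit every day over the whole season (used by validation runs)."""
    return np.arange(0, config.season_days + 1)


def _observe(
    events: _PlantEvents, visits: np.ndarray, harvest_first: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stage counts at each visit day under one reporting convention.

    Ripe fruits are harvested at the first visit on or after ripening,
    provided they have not been lost by then.  A count-first reporter counts
    fruits before harvesting and reports the previous visit's harvest in the
    harvested column; a harvest-first reporter harvests, reports today's
    harvest, and counts what remains.
    """
    open_day, open_end = events.open_day, events.open_end
    fade_end, converts = events.fade_end, events.converts
    ripe_day, loss_day = events.ripe_day, events.loss_day

    # harvest day per fruit: first visit >= ripe_day that precedes loss
    harvest_day = np.full(open_day.shape, np.iinfo(np.int64).max // 2)
    if converts.any() and len(visits):
        idx = np.searchsorted(visits, ripe_day, side="left")
        can = converts & (idx < len(visits))
        v = visits[np.minimum(idx, len(visits) - 1)]
        ok = can & (v < loss_day)
        harvest_day[ok] = v[ok]

    O = np.empty(len(visits), dtype=int)
    F = np.empty(len(visits), dtype=int)
    R = np.empty(len(visits), dtype=int)
    H = np.empty(len(visits), dtype=int)
    prev = None
    for i, d in enumerate(visits):
        O[i] = int(np.sum((open_day <= d) & (d < open_end)))
        F[i] = int(np.sum(~converts & (open_end <= d) & (d < fade_end)))
        on_plant = converts & (open_end <= d) & (loss_day > d)
        if harvest_first:
            R[i] = int(np.sum(on_plant & (harvest_day > d)))
            H[i] = int(np.sum(harvest_day == d))
        else:
            R[i] = int(np.sum(on_plant & (harvest_day >= d)))
            H[i] = 0 if prev is None else int(np.sum(harvest_day == prev))
        prev = d
    return O, F, R, H


def _pick_type(rng, type_mix: Mapping[str, float]) -> str:
    names = sorted(type_mix)
    probs = np.array([type_mix[t] for t in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _pick_crop(rng, config: SimulationConfig) -> tuple[str, str]:
    if rng.random() < config.group_mix:
        crops = CUCURBIT_CROPS
    else:
        crops = SELFING_CROPS
    crop = crops[int(rng.integers(0, len(crops)))]
    return crop, CROP_GROUPS[crop]


def simulate_study(
    config: SimulationConfig,
    include_sheets: bool = True,
    schedule_override: np.ndarray | None = None,
) -> SimulatedStudy:
    """Generate a full synthetic study.

    ``schedule_override`` forces every plant onto one fixed visit schedule
    (e.g. :func:`daily_schedule`) instead of drawing per-type schedules;
    ``include_sheets=False`` skips sheet generation entirely (the recorded
    truth is identical either way, because the truth draws precede the
    observation draws in each plant's RNG stream).
    """
    gardens, intercepts = _draw_gardens(config)
    sheets: list[ObservationSeries] = []
    truth_rows: list[dict] = []

    for g, garden in enumerate(gardens):
        for p in range(config.plants_per_garden):
            rng = np.random.default_rng([config.seed, g, p])
            plant_id = f"{garden.garden_id}-P{p + 1:03d}"

            crop, group = _pick_crop(rng, config)
            p_convert = conversion_probability(config, garden, intercepts[g], group)
            events = _simulate_flowers(rng, config, p_convert)
            n_flowers = len(events.open_day)
            n_fruits = int(events.converts.sum())

            truth_rows.append(
                {
                    "plant_id": plant_id,
                    "garden_id": garden.garden_id,
                    "year": garden.year,
                    "crop": crop,
                    "plant_group": group,
                    "true_flowers_bloomed": n_flowers,
                    "true_fruits_set": n_fruits,
                    "true_fruit_set_pct": (
                        100.0 * n_fruits / n_flowers if n_flowers else np.nan
                    ),
                    "p_conversion": p_convert,
                    "garden_intercept": float(intercepts[g]),
                }
            )

            if not include_sheets:
                continue

            ptype = _pick_type(rng, config.type_mix)
            if schedule_override is not None:
                visits = np.asarray(schedule_override)
            elif ptype == "once":
                visits = np.array([int(rng.integers(0, config.season_days))])
            else:
                visits = _draw_schedule(
                    rng, config.schedules[ptype], config.season_days
                )
            harvest_first = rng.random() < config.harvest_mode_mix
            O, F, R, H = _observe(events, visits, harvest_first)

            comments: dict[int, str] = {}
            for cat in sorted(config.comment_rates):
                if rng.random() < config.comment_rates[cat] and len(visits) > 0:
                    at = int(rng.integers(0, len(visits)))
                    phrase = _COMMENT_PHRASES[cat]
                    comments[at] = (
                        f"{comments[at]} {phrase}" if at in comments else phrase
                    )

            records = [
                ObservationRecord(
                    visit_date=SEASON_START + _dt.timedelta(days=int(d)),
                    open_flowers=int(O[i]),
                    faded_flowers=int(F[i]),
                    fruits_on_plant=int(R[i]),
                    fruits_harvested=int(H[i]),
                    comment=comments.get(i),
                )
                for i, d in enumerate(visits)
            ]
            sheets.append(
                ObservationSeries(
                    plant_id=plant_id,
                    garden_id=garden.garden_id,
                    year=garden.year,
                    crop=crop,
                    crop_raw=crop,
                    records=records,
                )
            )

    truth = pd.DataFrame(truth_rows)
    study = SimulatedStudy(sheets=sheets, gardens=gardens, truth=truth, config=config)
    if include_sheets and any(r > 0 for r in config.error_rates.values()):
        study.sheets, study.corruption_log = inject_errors(
            study.sheets, config.error_rates, config.seed
        )
    return study


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


def inject_errors(
    sheets: Sequence[ObservationSeries],
    error_rates: Mapping[str, float],
    seed: int,
) -> tuple[list[ObservationSeries], dict[str, str]]:
    """Apply at most one labelled corruption per series.

    For each series, one uniform draw per error type is consumed in the
    canonical order ``unknown_crop, too_few_visits, initial_fruit,
    implausible``; the first type whose draw falls under its rate is
    applied.  Rates of zero make this a no-op that still leaves the input
    untouched (a fresh list is returned either way).
    """
    for name in error_rates:
        if name not in ERROR_TYPES:
            raise ConfigurationError(f"error_rates: unknown error type {name!r}")
    rng = np.random.default_rng([seed, 777_000_001])
    out: list[ObservationSeries] = []
    log: dict[str, str] = {}
    for series in sheets:
        draws = rng.random(len(ERROR_TYPES))
        chosen = None
        for i, etype in enumerate(ERROR_TYPES):
            if draws[i] < error_rates.get(etype, 0.0):
                chosen = etype
                break
        if chosen is None:
            out.append(series)
            continue
        out.append(_corrupt(series, chosen))
        log[series.plant_id] = chosen
    return out, log


def _corrupt(series: ObservationSeries, etype: str) -> ObservationSeries:
    records = list(series.records)
    crop = series.crop
    crop_raw = series.crop_raw
    if etype == "unknown_crop":
        crop, crop_raw = "other", "physalis"
    elif etype == "too_few_visits":
        records = records[: min(2, len(records))]
    elif etype == "initial_fruit":
        records[0] = dataclasses.replace(records[0], fruits_on_plant=2)
    elif etype == "implausible":
        # a sign typo in a count column, caught by the plausibility criterion
        mid = len(records) // 2
        records[mid] = dataclasses.replace(records[mid], open_flowers=-3)
    return ObservationSeries(
        plant_id=series.plant_id,
        garden_id=series.garden_id,
        year=series.year,
        crop=crop,
        crop_raw=crop_raw,
        records=records,
    )


def truth_to_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
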