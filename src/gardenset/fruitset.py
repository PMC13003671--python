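"""Fruit-set reconstruction from interval censuses, and quality control.

A gardener visits a plant every few days and records four counts: open
flowers ``O_t``, faded flowers ``F_t``, fruits on the plant ``R_t`` and
fruits harvested since the previous visit ``H_t``.  Fruit set is the
percentage of flowers that bloomed on the plant which developed into
fruits::

    fruit set (%) = 100 * total_fruits / total_flowers

Neither total is observed directly; both are reconstructed from the
interval censuses.

Fruits.  New fruits in the interval ending at visit ``t`` are
``n_fruit_t = max(0, R_t + H_t - R_{t-1})``.  Gardeners differed in whether
they harvested before or after counting (harvest-first vs count-first
reporting), but at interval level both conventions reduce to this single
formula — the reporting mode only changes which plausibility checks apply.
Negative differences indicate fruit loss between visits and contribute
nothing (clipped at zero), which also guarantees a fruit that sits on the
plant across several visits is counted once.

Flowers.  Each flower is a unit that is, at any visit, open, faded, or
already converted to a (possibly harvested) fruit.  With cumulative
reconstructed fruits ``C_t``, the visible unit total is
``U_t = O_t + F_t + C_t`` and new flower units are the clipped increments
``n_t = max(0, U_t - U_{t-1})`` (with ``n_0 = U_0`` so flowers already
present at the first visit are counted).  This conservation form adds every
fruit or faded flower whose emergence from an earlier stage was never
observed, and never double-counts a flower that persists across visits.
Because pollination of flowers that newly opened or faded at the final
visit cannot be verified, the stage-wise increments
``max(0, ΔO_T) + max(0, ΔF_T)`` are subtracted from the total.

Units can also vanish unobserved (a faded flower drops off between two
visits while another opens), so the reconstruction is a lower bound on the
true number of flowers that bloomed — exact when every stage transition is
visible at some visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import MissingCountError, UndefinedFruitSetError
from .sheets import GardenContext, ObservationSeries, STUDY_CROPS

HarvestMode = Literal["count-first", "harvest-first"]

#: Comment fragments that count as an explicit statement that the gardener
#: harvested fruits before counting.
HARVEST_FIRST_HINTS = (
    "harvest first",
    "harvested before counting",
    "harvested first",
    "zuerst geerntet",
    "vor dem zählen geerntet",
)


@dataclass
class FlowerFruitLedger:
    """Interval-by-interval accounting behind a fruit-set value."""

    new_fruits: list[int]          # n_fruit_t per visit
    cumulative_fruits: list[int]   # C_t
    flower_units: list[int]        # U_t = O_t + F_t + C_t
    new_units: list[int]           # n_t (n_0 = U_0)
    last_visit_subtraction: int    # s_T
    warnings: list[str] = field(default_factory=list)


@dataclass
class FruitSetResult:
    plant_id: str
    total_fruits: int
    total_flowers: int
    fruit_set_pct: float
    harvest_mode: HarvestMode
    ledger: FlowerFruitLedger | None = None
    warnings: list[str] = field(default_factory=list)


def detect_harvest_mode(series: ObservationSeries) -> HarvestMode:
    """Classify a series as harvest-first or count-first reporting.

    Harvest-first iff some visit reports strictly more harvested fruits than
    fruits on the plant, or a comment explicitly says so.  Gardeners are
    assumed consistent, so the whole series gets one mode.
    """
    for rec in series.records:
        h, r = rec.fruits_harvested, rec.fruits_on_plant
        if h is not None and r is not None and h > r:
            return "harvest-first"
        if rec.comment:
            text = rec.comment.lower()
            if any(hint in text for hint in HARVEST_FIRST_HINTS):
                return "harvest-first"
    return "count-first"


def _require_counts(series: ObservationSeries, columns: Sequence[str]) -> None:
    for i, rec in enumerate(series.records):
        for col in columns:
            if getattr(rec, col) is None:
                raise MissingCountError(
                    f"series {series.plant_id}: visit {i} "
                    f"({rec.visit_date.isoformat()}) has no {col} count"
                )


def total_fruits(
    series: ObservationSeries, mode: HarvestMode | None = None
) -> tuple[int, FlowerFruitLedger]:
    """Reconstruct the total number of fruits and start the ledger.

    ``C_0 = R_0 + H_0`` (fruits already present or harvested at the first
    visit are counted — quality criterion 3 rejects such series anyway), and
    ``n_fruit_t = max(0, R_t + H_t - R_{t-1})`` afterwards.  The reporting
    mode only adds plausibility warnings: a count-first reporter can never
    truthfully harvest more in an interval than was on the plant at its
    start.
    """
    if series.n_visits < 2:
        raise MissingCountError(
            f"series {series.plant_id}: at least two visits are needed to "
            "reconstruct fruits"
        )
    if mode is None:
        mode = detect_harvest_mode(series)
    _require_counts(series, ("fruits_on_plant", "fruits_harvested"))
    R = [rec.fruits_on_plant for rec in series.records]
    H = [rec.fruits_harvested for rec in series.records]

    warnings_: list[str] = []
    new_fruits = [R[0] + H[0]]
    cumulative = [new_fruits[0]]
    for t in range(1, len(R)):
        diff = R[t] + H[t] - R[t - 1]
        if diff < 0:
            warnings_.append(
                f"visit {t}: negative fruit difference ({diff}) treated as "
                "fruit loss, no additional fruit"
            )
        if mode == "count-first" and H[t] > R[t - 1]:
            warnings_.append(
                f"visit {t}: harvested {H[t]} exceeds fruits on plant at the "
                f"previous visit ({R[t - 1]}) under count-first reporting"
            )
        new_fruits.append(max(0, diff))
        cumulative.append(cumulative[-1] + new_fruits[-1])

    ledger = FlowerFruitLedger(
        new_fruits=new_fruits,
        cumulative_fruits=cumulative,
        flower_units=[],
        new_units=[],
        last_visit_subtraction=0,
        warnings=warnings_,
    )
    return cumulative[-1], ledger


def total_flowers(series: ObservationSeries, ledger: FlowerFruitLedger) -> int:
    """Reconstruct the number of flowers that bloomed, completing the ledger."""
    _require_counts(series, ("open_flowers", "faded_flowers"))
    O = [rec.open_flowers for rec in series.records]
    F = [rec.faded_flowers for rec in series.records]
    C = ledger.cumulative_fruits
    if len(C) != len(O):
        raise ValueError("ledger does not match series length")

    U = [O[t] + F[t] + C[t] for t in range(len(O))]
    new_units = [U[0]]
    for t in range(1, len(U)):
        new_units.append(max(0, U[t] - U[t - 1]))

    # flowers newly opened or newly faded at the last visit: pollination
    # success cannot be verified, so they are subtracted.  New fruits at the
    # last visit are verified pollinations and stay.
    T = len(U) - 1
    s_T = max(0, O[T] - O[T - 1]) + max(0, F[T] - F[T - 1]) if T >= 1 else 0

    ledger.flower_units = U
    ledger.new_units = new_units
    ledger.last_visit_subtraction = s_T

    total = sum(new_units) - s_T
    if total < 0:
        ledger.warnings.append(
            "last-visit subtraction exceeded the unit total; flower total "
            "floored at 0"
        )
        total = 0
    return total


def compute_fruit_set(
    series: ObservationSeries, mode: HarvestMode | None = None
) -> FruitSetResult:
    """Compose fruit and flower reconstruction into a fruit-set percentage.

    Raises :class:`UndefinedFruitSetError` when no flower ever bloomed —
    0/0 is not a fruit set of zero.  A fruit set above 100% is possible on
    implausible sheets and is warned about, not capped; quality criterion 4
    is the intended guard.
    """
    if mode is None:
        mode = detect_harvest_mode(series)
    fruits, ledger = total_fruits(series, mode)
    flowers = total_flowers(series, ledger)
    warnings_ = list(ledger.warnings)

    if flowers == 0:
        if fruits > 0:
            raise UndefinedFruitSetError(
                f"series {series.plant_id}: {fruits} fruits reconstructed but "
                "no flowers — implausible series"
            )
        raise UndefinedFruitSetError(
            f"series {series.plant_id}: no flower ever bloomed; fruit set "
            "undefined (not 0%)"
        )
    pct = 100.0 * fruits / flowers
    if pct > 100.0:
        warnings_.append(f"fruit set {pct:.1f}% exceeds 100%")
    return FruitSetResult(
        plant_id=series.plant_id,
        total_fruits=fruits,
        total_flowers=flowers,
        fruit_set_pct=pct,
        harvest_mode=mode,
        ledger=ledger,
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

CRITERION_LABELS = {
    1: "observed plant is one of the eight selected crops",
    2: "observation series includes at least three measurements",
    3: "no fruit at the first measurement",
    4: "observation series is plausible and without errors",
    5: "at least three study plants per garden and year",
}


@dataclass
class SpikeRule:
    """Single-point irregularity pre-pass (off by default).

    A record is dropped when, in any count column, its value differs from
    *both* neighbours by more than ``multiplier`` times the column's robust
    step scale (the median absolute successive difference of the remaining
    steps, floored at 1).  Mirrors the manual removal of single implausible
    points such as typos in the harvested-fruit column.
    """

    multiplier: float = 5.0


@dataclass
class QualityReport:
    plant_id: str
    passed: bool
    first_failed_criterion: int | None
    criteria: dict[int, bool]          # criterion number -> passed
    excluded_points: list[int] = field(default_factory=list)
    detail: str = ""


def _spike_pass(series: ObservationSeries, rule: SpikeRule) -> ObservationSeries:
    from statistics import median

    n = series.n_visits
    if n < 3:
        return series
    drop: set[int] = set()
    for col in ("open_flowers", "faded_flowers", "fruits_on_plant", "fruits_harvested"):
        values = [getattr(r, col) for r in series.records]
        if any(v is None for v in values):
            continue
        steps = [abs(b - a) for a, b in zip(values, values[1:])]
        for t in range(1, n - 1):
            lo = abs(values[t] - values[t - 1])
            hi = abs(values[t] - values[t + 1])
            # scale from the steps not touching the candidate point itself
            others = steps[: t - 1] + steps[t + 1 :]
            scale = max(1.0, median(others)) if others else 1.0
            if lo > rule.multiplier * scale and hi > rule.multiplier * scale:
                drop.add(t)
    if not drop:
        return series
    kept = [r for t, r in enumerate(series.records) if t not in drop]
    trimmed = ObservationSeries(
        plant_id=series.plant_id,
        garden_id=series.garden_id,
        year=series.year,
        crop=series.crop,
        crop_raw=series.crop_raw,
        records=kept,
    )
    trimmed._dropped_points = sorted(drop)  # type: ignore[attr-defined]
    return trimmed


def _plausible(series: ObservationSeries) -> tuple[bool, str]:
    """Criterion 4: fruits without flowers, missing counts, negative counts,
    duplicate dates."""
    for i, rec in enumerate(series.records):
        for col in ("open_flowers", "faded_flowers", "fruits_on_plant", "fruits_harvested"):
            v = getattr(rec, col)
            if v is None:
                return False, f"missing {col} at visit {i}"
            if v < 0:
                return False, f"negative {col} at visit {i}"
    dates = series.dates
    if len(set(dates)) != len(dates):
        return False, "duplicate visit dates"
    try:
        result = compute_fruit_set(series)
    except MissingCountError:
        return False, "too few visits to reconstruct totals"
    except UndefinedFruitSetError as exc:
        if "implausible" in str(exc):
            return False, "reconstructed fruits but no flowers"
        return True, ""  # zero flowers and zero fruits: empty but not an error
    if result.total_flowers == 0 and result.total_fruits > 0:
        return False, "reconstructed fruits but no flowers"
    return True, ""


def apply_quality_criteria(
    all_series: Iterable[ObservationSeries],
    gardens: Iterable[GardenContext] | None = None,
    spike_rule: SpikeRule | None = None,
    min_plants_per_garden_year: int = 3,
) -> list[QualityReport]:
    """Apply the five sequential data-quality criteria to a whole study.

    Criteria, in order: (1) crop is on the study list; (2) at least three
    measurements; (3) no fruit at the first measurement (``R_0 = 0`` and
    ``H_0 = 0``); (4) the series is plausible and without errors; (5) after
    1–4, at least three surviving plants per garden and year — gardens below
    that lose all of that year's plants.  Each series is attributed to its
    *first* failing criterion, so per-criterion exclusion counts sum to the
    total number of exclusions.

    The optional spike rule removes single irregular records before the
    criteria run; it is off by default.
    """
    del gardens  # replication is judged from the series themselves
    reports: list[QualityReport] = []
    survivors: list[ObservationSeries] = []

    for original in all_series:
        series = original
        excluded_points: list[int] = []
        if spike_rule is not None:
            series = _spike_pass(series, spike_rule)
            excluded_points = getattr(series, "_dropped_points", [])

        criteria: dict[int, bool] = {}
        detail = ""

        criteria[1] = series.crop in STUDY_CROPS
        if not criteria[1]:
            detail = f"crop {series.crop_raw!r} is not a study crop"
        criteria[2] = series.n_visits >= 3
        first = series.records[0]
        criteria[3] = (first.fruits_on_plant or 0) == 0 and (
            first.fruits_harvested or 0
        ) == 0
        if criteria[1] and criteria[2] and criteria[3]:
            criteria[4], c4_detail = _plausible(series)
            detail = detail or c4_detail
        else:
            # later criteria are still reported for completeness
            criteria[4], _ = _plausible(series)
        criteria[5] = True  # provisional; resolved across series below

        first_fail = next((c for c in (1, 2, 3, 4) if not criteria[c]), None)
        report = QualityReport(
            plant_id=series.plant_id,
            passed=first_fail is None,
            first_failed_criterion=first_fail,
            criteria=criteria,
            excluded_points=excluded_points,
            detail=detail,
        )
        reports.append(report)
        if first_fail is None:
            survivors.append(series)

    # criterion 5: garden-year replication among the survivors of 1-4
    counts: dict[tuple[str, int], int] = {}
    for s in survivors:
        counts[(s.garden_id, s.year)] = counts.get((s.garden_id, s.year), 0) + 1
    weak = {k for k, v in counts.items() if v < min_plants_per_garden_year}
    by_id = {s.plant_id: s for s in survivors}
    for report in reports:
        if not report.passed:
            continue
        s = by_id[report.plant_id]
        if (s.garden_id, s.year) in weak:
            report.criteria[5] = False
            report.passed = False
            report.first_failed_criterion = 5
            report.detail = (
                f"garden {s.garden_id} ({s.year}) has only "
                f"{counts[(s.garden_id, s.year)]} surviving plant(s)"
            )
    return reports


def exclusion_table(reports: Sequence[QualityReport]) -> pd.DataFrame:
    """Per-criterion exclusion counts under first-fail attribution."""
    rows = []
    for c in (1, 2, 3, 4, 5):
        n = sum(1 for r in reports if r.first_failed_criterion == c)
        rows.append({"criterion": c, "description": CRITERION_LABELS[c], "excluded": n})
    rows.append(
        {
            "criterion": "total",
            "description": "all criteria",
            "excluded": sum(1 for r in reports if not r.passed),
        }
    )
    return pd.DataFrame(rows)


def fruit_set_table(
    all_series: Iterable[ObservationSeries],
    reports: Sequence[QualityReport] | None = None,
    only_passing: bool = True,
) -> pd.DataFrame:
    """Per-plant fruit-set results as a flat table.

    With ``only_passing`` (the default) series failing QC are skipped;
    series whose fruit set is undefined (no flowers) are always skipped
    with their plant id recorded in the ``dropped`` attribute.
    """
    passed = (
        {r.plant_id for r in reports if r.passed} if reports is not None else None
    )
    rows = []
    dropped: list[str] = []
    for s in all_series:
        if only_passing and passed is not None and s.plant_id not in passed:
            continue
        try:
            res = compute_fruit_set(s)
        except (UndefinedFruitSetError, MissingCountError):
            dropped.append(s.plant_id)
            continue
        rows.append(
            {
                "plant_id": s.plant_id,
                "garden_id": s.garden_id,
                "year": s.year,
                "crop": s.crop,
                "plant_group": s.plant_group,
                "total_fruits": res.total_fruits,
                "total_flowers": res.total_flowers,
                "fruit_set_pct": res.fruit_set_pct,
                "harvest_mode": res.harvest_mode,
                "n_warnings": len(res.warnings),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "plant_id",
            "garden_id",
            "year",
            "crop",
            "plant_group",
            "total_fruits",
            "total_flowers",
            "fruit_set_pct",
            "harvest_mode",
            "n_warnings",
        ],
    )
    table.attrs["dropped"] = dropped
    return table
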