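"""Reading, validating and writing observation sheets and garden tables.

The observation sheet is the tabular form a gardener fills in on each visit
to a study plant: the date plus four stage counts — open flowers, faded
flowers, fruits currently on the plant, and fruits harvested since the
previous visit — and an optional free-text comment.  One plant's visits,
ordered by date, form an :class:`ObservationSeries`.

Garden-level covariates (bee richness/abundance, landscape imperviousness,
growing-season temperature, size, city, year) live in a separate table with
one row per garden and year, parsed into :class:`GardenContext`.

All counts are non-negative integers by contract.  Blank cells are read as
*missing*, never as zero, and non-integer cells are reported as row
problems, never rounded.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

#: Crops gardeners were asked to choose from, with the plant-group split used
#: throughout the analysis.  Cucumber, pumpkin and zucchini are monoecious and
#: strongly insect-pollination dependent; the second group (tomato, pepper,
#: pepperoni, chili, plus strawberry) is capable of self-pollination.
CROP_GROUPS: dict[str, str] = {
    "cucumber": "Cucurbitaceae",
    "zucchini": "Cucurbitaceae",
    "pumpkin": "Cucurbitaceae",
    "tomato": "Solanaceae",
    "pepper": "Solanaceae",
    "pepperoni": "Solanaceae",
    "chili": "Solanaceae",
    "strawberry": "Solanaceae",
}

STUDY_CROPS: tuple[str, ...] = tuple(CROP_GROUPS)

#: Free-text crop names (German and English) mapped onto canonical crop names.
#: Gardeners wrote crop names by hand, so matching is case-insensitive and the
#: table is meant to be extended by users.  Anything unmatched becomes "other".
DEFAULT_CROP_SYNONYMS: dict[str, str] = {
    **{c: c for c in STUDY_CROPS},
    "gurke": "cucumber",
    "gurken": "cucumber",
    "salatgurke": "cucumber",
    "zuchini": "zucchini",
    "zucchetti": "zucchini",
    "kuerbis": "pumpkin",
    "kürbis": "pumpkin",
    "hokkaido": "pumpkin",
    "erdbeere": "strawberry",
    "erdbeeren": "strawberry",
    "tomate": "tomato",
    "tomaten": "tomato",
    "cherrytomate": "tomato",
    "cherry tomato": "tomato",
    "paprika": "pepper",
    "chilli": "chili",
    "peperoni": "pepperoni",
}

OBSERVATION_COLUMNS = (
    "plant_id",
    "garden_id",
    "year",
    "crop",
    "visit_date",
    "visit_time",
    "observer",
    "open_flowers",
    "faded_flowers",
    "fruits_on_plant",
    "fruits_harvested",
    "comment",
)
_REQUIRED_OBS_COLUMNS = (
    "plant_id",
    "garden_id",
    "year",
    "crop",
    "visit_date",
    "open_flowers",
    "faded_flowers",
    "fruits_on_plant",
    "fruits_harvested",
)

GARDEN_COLUMNS = (
    "garden_id",
    "city",
    "year",
    "size_ha",
    "imperviousness_pct",
    "mean_temp_c",
    "bee_richness",
    "bee_abundance",
)

COUNT_COLUMNS = (
    "open_flowers",
    "faded_flowers",
    "fruits_on_plant",
    "fruits_harvested",
)


@dataclass(frozen=True)
class ObservationRecord:
    """One gardener visit: the four stage counts plus metadata.

    ``fruits_harvested`` is the number of fruits removed since the previous
    visit (per-visit, not cumulative).  ``None`` counts mean the cell was
    blank on the sheet.
    """

    visit_date: _dt.date
    open_flowers: int | None
    faded_flowers: int | None
    fruits_on_plant: int | None
    fruits_harvested: int | None
    visit_time: str | None = None
    observer: str | None = None
    comment: str | None = None

    def counts(self) -> tuple[int | None, int | None, int | None, int | None]:
        return (
            self.open_flowers,
            self.faded_flowers,
            self.fruits_on_plant,
            self.fruits_harvested,
        )


@dataclass
class ObservationSeries:
    """The ordered visit records for one study plant."""

    plant_id: str
    garden_id: str
    year: int
    crop: str
    records: list[ObservationRecord]
    crop_raw: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError(f"series {self.plant_id}: needs at least one record")
        dates = [r.visit_date for r in self.records]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValidationError(
                f"series {self.plant_id}: visit dates must be strictly increasing"
            )

    @property
    def plant_group(self) -> str:
        """Plant-group label; crops outside the study list map to 'other'."""
        return CROP_GROUPS.get(self.crop, "other")

    @property
    def n_visits(self) -> int:
        return len(self.records)

    @property
    def dates(self) -> list[_dt.date]:
        return [r.visit_date for r in self.records]

    def comments(self) -> list[str]:
        return [r.comment for r in self.records if r.comment]


@dataclass(frozen=True)
class GardenContext:
    """Garden-year covariates used in the mixed models.

    imperviousness_pct is percent sealed surface within a 1000 m radius
    buffer; mean_temp_c is the mean of daily average air temperatures over
    June–September; richness and abundance both include the managed honeybee.
    """

    garden_id: str
    city: str
    year: int
    size_ha: float
    imperviousness_pct: float
    mean_temp_c: float
    bee_richness: int
    bee_abundance: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.imperviousness_pct <= 100.0:
            raise ValidationError(
                f"garden {self.garden_id} ({self.year}): imperviousness_pct "
                f"{self.imperviousness_pct} outside [0, 100]"
            )
        if self.size_ha <= 0:
            raise ValidationError(
                f"garden {self.garden_id} ({self.year}): size_ha must be positive"
            )
        if self.bee_richness > 0 and self.bee_abundance > 0:
            if self.bee_richness > self.bee_abundance:
                raise ValidationError(
                    f"garden {self.garden_id} ({self.year}): bee_richness "
                    f"{self.bee_richness} exceeds bee_abundance {self.bee_abundance}"
                )


@dataclass(frozen=True)
class RowProblem:
    """A single cell or row that could not be parsed cleanly."""

    row: int
    plant_id: str
    column: str
    value: str
    message: str


@dataclass
class SheetReadResult:
    series: list[ObservationSeries]
    problems: list[RowProblem] = field(default_factory=list)

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)


def canonical_crop(name: str | None, synonyms: Mapping[str, str] | None = None) -> str:
    """Map a free-text crop name to a canonical crop, or 'other'."""
    if synonyms is None:
        synonyms = DEFAULT_CROP_SYNONYMS
    if name is None:
        return "other"
    key = str(name).strip().lower()
    return synonyms.get(key, "other")


def _parse_count(value, row: int, plant_id: str, column: str, problems: list) -> int | None:
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none"}:
        return None
    try:
        number = int(text)
    except ValueError:
        problems.append(
            RowProblem(row, plant_id, column, text, "count is not an integer")
        )
        return None
    if number < 0:
        # kept as-is: negative counts are a plausibility failure, not a parse one
        problems.append(RowProblem(row, plant_id, column, text, "negative count"))
    return number


def _parse_date(value, row: int, plant_id: str, problems: list) -> _dt.date | None:
    text = str(value).strip() if value is not None else ""
    if not text or text.lower() == "nan":
        problems.append(RowProblem(row, plant_id, "visit_date", text, "missing date"))
        return None
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        problems.append(
            RowProblem(row, plant_id, "visit_date", text, "unparseable ISO date")
        )
        return None


def read_observation_sheets(
    path: str | Path,
    synonyms: Mapping[str, str] | None = None,
) -> SheetReadResult:
    """Read an observation-sheet CSV into one series per plant.

    Rows are sorted by visit date (a warning is emitted if the file was out
    of order); blank counts become missing values; cells that cannot be
    parsed are collected as :class:`RowProblem` entries rather than raised,
    so that quality control can attribute them.  Duplicate
    ``(plant_id, visit_date)`` pairs raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for optional in ("visit_time", "observer", "comment"):
        if optional not in df.columns:
            df[optional] = ""

    problems: list[RowProblem] = []
    rows: list[dict] = []
    for i, raw in enumerate(df.to_dict("records")):
        plant_id = str(raw["plant_id"]).strip()
        date = _parse_date(raw["visit_date"], i, plant_id, problems)
        if date is None:
            continue
        counts = {
            col: _parse_count(raw[col], i, plant_id, col, problems)
            for col in COUNT_COLUMNS
        }
        rows.append(
            {
                "plant_id": plant_id,
                "garden_id": str(raw["garden_id"]).strip(),
                "year": int(str(raw["year"]).strip()),
                "crop_raw": str(raw["crop"]).strip(),
                "date": date,
                "visit_time": str(raw["visit_time"]).strip() or None,
                "observer": str(raw["observer"]).strip() or None,
                "comment": str(raw["comment"]).strip() or None,
                **counts,
            }
        )

    seen: dict[tuple[str, _dt.date], int] = {}
    duplicates = []
    for r in rows:
        key = (r["plant_id"], r["date"])
        if key in seen:
            duplicates.append(key)
        seen[key] = 1
    if duplicates:
        raise ValidationError(
            "duplicate (plant_id, visit_date) rows: "
            + ", ".join(f"{p}@{d.isoformat()}" for p, d in duplicates)
        )

    series: list[ObservationSeries] = []
    by_plant: dict[str, list[dict]] = {}
    order: list[str] = []
    for r in rows:
        if r["plant_id"] not in by_plant:
            order.append(r["plant_id"])
        by_plant.setdefault(r["plant_id"], []).append(r)
    for plant_id in order:
        plant_rows = by_plant[plant_id]
        sorted_rows = sorted(plant_rows, key=lambda r: r["date"])
        if sorted_rows != plant_rows:
            warnings.warn(
                f"series {plant_id}: visit dates were out of order and have "
                "been sorted",
                stacklevel=2,
            )
        records = [
            ObservationRecord(
                visit_date=r["date"],
                open_flowers=r["open_flowers"],
                faded_flowers=r["faded_flowers"],
                fruits_on_plant=r["fruits_on_plant"],
                fruits_harvested=r["fruits_harvested"],
                visit_time=r["visit_time"],
                observer=r["observer"],
                comment=r["comment"],
            )
            for r in sorted_rows
        ]
        first = sorted_rows[0]
        series.append(
            ObservationSeries(
                plant_id=plant_id,
                garden_id=first["garden_id"],
                year=first["year"],
                crop=canonical_crop(first["crop_raw"], synonyms),
                crop_raw=first["crop_raw"],
                records=records,
            )
        )
    return SheetReadResult(series=series, problems=problems)


def series_to_frame(series: Iterable[ObservationSeries]) -> pd.DataFrame:
    """Flatten series back into the external observation CSV schema."""
    rows = []
    for s in series:
        for r in s.records:
            rows.append(
                {
                    "plant_id": s.plant_id,
                    "garden_id": s.garden_id,
                    "year": s.year,
                    "crop": s.crop_raw if s.crop_raw is not None else s.crop,
                    "visit_date": r.visit_date.isoformat(),
                    "visit_time": r.visit_time or "",
                    "observer": r.observer or "",
                    "open_flowers": "" if r.open_flowers is None else r.open_flowers,
                    "faded_flowers": "" if r.faded_flowers is None else r.faded_flowers,
                    "fruits_on_plant": ""
                    if r.fruits_on_plant is None
                    else r.fruits_on_plant,
                    "fruits_harvested": ""
                    if r.fruits_harvested is None
                    else r.fruits_harvested,
                    "comment": r.comment or "",
                }
            )
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def write_observation_sheets(series: Iterable[ObservationSeries], path: str | Path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_garden_table(path: str | Path) -> list[GardenContext]:
    """Read the garden covariate table; one context per (garden_id, year)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GARDEN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dupes = df.duplicated(subset=["garden_id", "year"])
    if dupes.any():
        offenders = df.loc[dupes, ["garden_id", "year"]].to_records(index=False)
        raise ValidationError(f"duplicate (garden_id, year) rows: {list(offenders)}")
    contexts = []
    for row in df.to_dict("records"):
        contexts.append(
            GardenContext(
                garden_id=str(row["garden_id"]),
                city=str(row["city"]),
                year=int(row["year"]),
                size_ha=float(row["size_ha"]),
                imperviousness_pct=float(row["imperviousness_pct"]),
                mean_temp_c=float(row["mean_temp_c"]),
                bee_richness=int(row["bee_richness"]),
                bee_abundance=int(row["bee_abundance"]),
            )
        )
    return contexts


def gardens_to_frame(gardens: Iterable[GardenContext]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "garden_id": g.garden_id,
                "city": g.city,
                "year": g.year,
                "size_ha": g.size_ha,
                "imperviousness_pct": g.imperviousness_pct,
                "mean_temp_c": g.mean_temp_c,
                "bee_richness": g.bee_richness,
                "bee_abundance": g.bee_abundance,
            }
            for g in gardens
        ],
        columns=list(GARDEN_COLUMNS),
    )


def write_garden_table(gardens: Iterable[GardenContext], path: str | Path) -> None:
    frame = gardens_to_frame(gardens)
    # shortest round-tripping repr keeps the write/read cycle exact
    for col in ("size_ha", "imperviousness_pct", "mean_temp_c"):
        frame[col] = frame[col].map(repr)
    frame.to_csv(path, index=False)


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write named result tables as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        target = outdir / f"{name}.csv"
        table.to_csv(target, index=False)
        written.append(target)
    return written
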