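"""Participation typology, long-break detection and comment coding.

Each monitored plant is one citizen-science contribution.  Duration ``D``
is the number of whole days between the first and last measurement;
frequency is ``D`` divided by the total number of measurements (days per
measurement).  The protocol asked for measurements every three to four
days over at least eight weeks, so contributions are split at 56 days of
duration (long iff D >= 56) and at an average interval of four days
(high frequency iff freq <= 4.0), giving four participation types;
single-observation contributions stand apart as "once".

Free-text comments are screened for three recurrent challenges (plant
health, harvest loss, protocol difficulties) plus plant death, via
deterministic case-insensitive keyword matching against an editable
German/English lexicon.  Keyword coding approximates what is inherently a
manual judgement, so outputs carry a provenance marker and are meant to be
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .sheets import ObservationSeries

ParticipationType = Literal["once", "short-low", "short-high", "long-low", "long-high"]

#: The four duration x frequency types, in reporting order.
PARTICIPATION_TYPES: tuple[str, ...] = (
    "short-low",
    "short-high",
    "long-low",
    "long-high",
)

LONG_DURATION_DAYS = 56       # eight weeks; D >= 56 counts as long
HIGH_FREQUENCY_DAYS = 4.0     # every four days or less counts as high
LONG_BREAK_DAYS = 10          # a break is a gap of strictly more than ten days

CHALLENGE_CATEGORIES = ("plant_health", "plant_death", "harvest_loss", "protocol")

#: Default keyword lexicon (lower-case substrings, German and English).
DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "plant_health": (
        "wither", "wilt", "weakened", "pest", "disease", "diseased", "mildew",
        "aphid", "fungus", "mice are eating", "sick", "yellow leaves",
        "krank", "welk", "schwach", "mehltau", "blattl", "pilz", "schädling",
    ),
    "plant_death": (
        "dead", "died", "dying", "tot", "abgestorben", "eingegangen",
        "vertrocknet",
    ),
    "harvest_loss": (
        "rotten", "rotted", "stolen", "theft", "eaten", "slug", "snail",
        "fruit fell", "fruit dropped", "fruit lost", "mold",
        "verfault", "faulig", "gestohlen", "diebstahl", "weggenommen",
        "schnecke", "abgefallen",
    ),
    "protocol": (
        "measurement", "miscount", "not sure", "unsure", "uncertain",
        "forgot", "vacation", "holiday", "no visit", "could not count",
        "correction", "must be",
        "messung", "unsicher", "vergessen", "urlaub", "korrektur",
        "nicht sicher", "verzählt",
    ),
}


@dataclass
class ParticipationProfile:
    plant_id: str
    n_measurements: int
    duration_days: int
    frequency: float            # days per measurement, D / n
    type: str
    has_break_gt10: bool


@dataclass
class CommentCodes:
    plant_id: str
    flags: dict[str, bool]
    matched_terms: list[str] = field(default_factory=list)
    has_comment: bool = False
    other: bool = False         # comments present but no challenge matched
    provenance: str = "keyword-matched"


def participation_profile(
    series: ObservationSeries,
    long_duration_days: int = LONG_DURATION_DAYS,
    high_frequency_days: float = HIGH_FREQUENCY_DAYS,
    interval_divisor: bool = False,
) -> ParticipationProfile:
    """Classify one contribution by duration and measurement frequency.

    ``interval_divisor`` switches the frequency denominator from the number
    of measurements ``n`` (the reporting convention used throughout) to the
    number of intervals ``n - 1``, for sensitivity analysis.
    """
    dates = series.dates
    n = len(dates)
    duration = (dates[-1] - dates[0]).days
    if n == 1:
        return ParticipationProfile(series.plant_id, 1, 0, 0.0, "once", False)
    divisor = (n - 1) if interval_divisor else n
    freq = duration / divisor
    dur_label = "long" if duration >= long_duration_days else "short"
    freq_label = "high" if freq <= high_frequency_days else "low"
    return ParticipationProfile(
        plant_id=series.plant_id,
        n_measurements=n,
        duration_days=duration,
        frequency=freq,
        type=f"{dur_label}-{freq_label}",
        has_break_gt10=detect_long_break(series),
    )


def detect_long_break(
    series: ObservationSeries, threshold_days: int = LONG_BREAK_DAYS
) -> bool:
    """True iff any gap between consecutive visits strictly exceeds the
    threshold (a ten-day gap is not a break; eleven days is)."""
    dates = series.dates
    return any((b - a).days > threshold_days for a, b in zip(dates, dates[1:]))


def code_comments(
    series: ObservationSeries,
    lexicon: Mapping[str, Sequence[str]] | None = None,
) -> CommentCodes:
    """Assign a contribution's comments to challenge categories by keywords."""
    if lexicon is None:
        lexicon = DEFAULT_LEXICON
    if not lexicon or not any(lexicon.values()):
        raise ConfigurationError("comment lexicon is empty")
    comments = [c.lower() for c in series.comments()]
    flags = {cat: False for cat in lexicon}
    matched: list[str] = []
    for text in comments:
        for cat, terms in lexicon.items():
            for term in terms:
                if term.lower() in text:
                    flags[cat] = True
                    matched.append(term)
    return CommentCodes(
        plant_id=series.plant_id,
        flags=flags,
        matched_terms=sorted(set(matched)),
        has_comment=bool(comments),
        other=bool(comments) and not any(flags.values()),
    )


def challenge_contingency(
    profiles: Iterable[ParticipationProfile],
    codes: Iterable[CommentCodes],
    category: str,
) -> pd.DataFrame:
    """4x2 table: participation types vs presence of a comment in a category.

    Single-observation contributions are excluded (they carry no type); all
    other contributions are included regardless of whether they passed the
    fruit-set quality criteria.
    """
    code_by_id = {c.plant_id: c for c in codes}
    table = pd.DataFrame(
        0,
        index=list(PARTICIPATION_TYPES),
        columns=["with_comment", "without_comment"],
    )
    table.index.name = "participation_type"
    for p in profiles:
        if p.type == "once":
            continue
        code = code_by_id.get(p.plant_id)
        flagged = bool(code and code.flags.get(category, False))
        table.loc[p.type, "with_comment" if flagged else "without_comment"] += 1
    return table


def profiles_table(profiles: Iterable[ParticipationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": p.plant_id,
                "n_measurements": p.n_measurements,
                "duration_days": p.duration_days,
                "frequency": p.frequency,
                "participation_type": p.type,
                "has_break_gt10": p.has_break_gt10,
            }
            for p in profiles
        ]
    )


def type_summary(profiles: Iterable[ParticipationProfile]) -> pd.DataFrame:
    """Count, mean duration and mean frequency per participation type."""
    df = profiles_table(profiles)
    df = df[df["participation_type"] != "once"]
    if df.empty:
        return pd.DataFrame(
            columns=["participation_type", "n", "duration_mean", "duration_sd",
                     "frequency_mean", "frequency_sd"]
        )
    grouped = (
        df.groupby("participation_type")
        .agg(
            n=("plant_id", "size"),
            duration_mean=("duration_days", "mean"),
            duration_sd=("duration_days", "std"),
            frequency_mean=("frequency", "mean"),
            frequency_sd=("frequency", "std"),
        )
        .reindex(PARTICIPATION_TYPES)
        .dropna(subset=["n"])
        .reset_index()
    )
    return grouped


def load_lexicon(path) -> dict[str, list[str]]:
    """Read a plain-text lexicon: ``category: term, term, ...`` per line."""
    lexicon: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ConfigurationError(f"lexicon line without category: {line!r}")
            cat, terms = line.split(":", 1)
            lexicon[cat.strip()] = [
                t.strip() for t in terms.split(",") if t.strip()
            ]
    if not lexicon:
        raise ConfigurationError(f"lexicon file {path} is empty")
    return lexicon
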