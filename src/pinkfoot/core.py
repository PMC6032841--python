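"""Domain types, CSV ingestion and winter-season calculus.

The study system is a flyway population of neck-collared geese wintering in
three well-separated regions: Jutland (Denmark), Friesland (the Netherlands)
and Flanders (Belgium).  A *wintering strategy* is the annual subset of these
regions an individual uses between autumn arrival and spring departure; the
seven nonempty subsets give seven strategies.  A *season* runs across the
calendar-year boundary and is labelled by its starting year (1991 means the
1991/1992 winter).
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Region",
    "Strategy",
    "STRATEGIES",
    "Resighting",
    "Bird",
    "SeasonYear",
    "WinterWindow",
    "season_of",
    "in_wintering_window",
    "read_resightings",
    "read_birds",
    "read_covariates",
    "write_resightings",
    "write_birds",
    "ReadReport",
]


class Region(enum.IntEnum):
    """The three major staging regions, ordered north to south."""

    JU = 0  # Jutland, Denmark
    FR = 1  # Friesland, the Netherlands
    FL = 2  # Flanders, Belgium

    @classmethod
    def from_code(cls, code: str) -> "Region":
        try:
            return cls[code.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown region code {code!r}; expected JU, FR or FL") from None


# Canonical labels use title-case two-letter fragments joined by hyphens.
_REGION_FRAG = {Region.JU: "Ju", Region.FR: "Fr", Region.FL: "Fl"}


@dataclass(frozen=True, order=True)
class Strategy:
    """A wintering strategy: a nonempty subset of the three regions.

    Exactly seven values exist.  ``label`` is the canonical string used in
    all serialization ("Ju", "Fr", "Fl", "Ju-Fr", "Ju-Fl", "Fr-Fl",
    "Ju-Fr-Fl"); region fragments always appear in north-to-south order.
    """

    regions: frozenset = field(compare=False)
    label: str = field(compare=True)

    def __post_init__(self):
        if not self.regions:
            raise ValueError("a strategy must use at least one region")

    @classmethod
    def from_regions(cls, regions: Iterable[Region]) -> "Strategy":
        rs = frozenset(Region(r) for r in regions)
        if not rs:
            raise ValueError("a strategy must use at least one region")
        label = "-".join(_REGION_FRAG[r] for r in sorted(rs))
        return cls(regions=rs, label=label)

    @classmethod
    def from_label(cls, label: str) -> "Strategy":
        frags = label.strip().split("-")
        inv = {v.lower(): k for k, v in _REGION_FRAG.items()}
        try:
            regions = [inv[f.lower()] for f in frags]
        except KeyError:
            raise ValueError(f"unknown strategy label {label!r}") from None
        if len(set(regions)) != len(regions):
            raise ValueError(f"repeated region in strategy label {label!r}")
        return cls.from_regions(regions)

    def __contains__(self, region: Region) -> bool:
        return region in self.regions

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def _all_strategies() -> tuple:
    out = []
    for mask in range(1, 8):
        regions = [r for r in Region if mask & (1 << r)]
        out.append(Strategy.from_regions(regions))
    # order: singletons first, then pairs, then the full set (stable, documented)
    out.sort(key=lambda s: (len(s.regions), sorted(s.regions)))
    return tuple(out)


#: The seven possible wintering strategies, in canonical order.
STRATEGIES: tuple = _all_strategies()
STRATEGY_BY_LABEL: Mapping[str, Strategy] = {s.label: s for s in STRATEGIES}


@dataclass(frozen=True, order=True)
class SeasonYear:
    """A winter season labelled by its starting calendar year."""

    start_year: int

    def __post_init__(self):
        if self.start_year < 1900:
            raise ValueError(f"implausible season start year {self.start_year}")

    def next(self) -> "SeasonYear":
        return SeasonYear(self.start_year + 1)

    def __int__(self) -> int:
        return self.start_year

    def __str__(self) -> str:
        return f"{self.start_year}/{self.start_year + 1}"


@dataclass(frozen=True)
class Resighting:
    """One dated field observation of a collared bird in a region."""

    bird_id: str
    date: dt.date
    region: Region

    def __post_init__(self):
        if not self.bird_id:
            raise ValueError("bird_id must be nonempty")


@dataclass(frozen=True)
class Bird:
    """Registry entry for one marked bird.

    ``age_at_ringing`` is "first_winter" for birds ringed in their first
    winter (known age thereafter) or "older" (unknown exact age, treated as
    adult).  ``breeding_status`` maps a season's start year to "brood" /
    "no_brood"; absent seasons are unknown.
    """

    bird_id: str
    ring_date: dt.date
    sex: str  # "M" | "F"
    age_at_ringing: str  # "first_winter" | "older"
    pair_id: str | None = None
    breeding_status: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.age_at_ringing not in ("first_winter", "older"):
            raise ValueError(f"bad age class {self.age_at_ringing!r}")

    @property
    def ring_season(self) -> SeasonYear:
        return season_of(self.ring_date)


def season_of(date: dt.date) -> SeasonYear:
    """Season containing ``date``; boundary July 1 (birds are on the
    breeding grounds mid-summer, so no winter observation is ambiguous)."""
    year = date.year if date.month >= 7 else date.year - 1
    return SeasonYear(year)


@dataclass(frozen=True)
class WinterWindow:
    """In-season date window used for strategy inference, closed at both
    ends.  Defaults bracket autumn arrival (late September onwards) and
    spring departure (through early May)."""

    start_month: int = 9
    start_day: int = 20
    end_month: int = 5
    end_day: int = 10

    def contains(self, date: dt.date) -> bool:
        m, d = date.month, date.day
        after_start = (m, d) >= (self.start_month, self.start_day)
        before_end = (m, d) <= (self.end_month, self.end_day)
        # window wraps the calendar-year boundary
        return after_start or before_end

    def sample_dates(self, season: SeasonYear):
        """(first, last) calendar dates of the window in ``season``."""
        first = dt.date(season.start_year, self.start_month, self.start_day)
        last = dt.date(season.start_year + 1, self.end_month, self.end_day)
        return first, last


DEFAULT_WINDOW = WinterWindow()


def in_wintering_window(date: dt.date, window: WinterWindow = DEFAULT_WINDOW) -> bool:
    """True iff ``date`` falls inside the wintering window (summer staging
    observations are excluded from strategy inference)."""
    return window.contains(date)


# ---------------------------------------------------------------------------
# CSV ingestion


@dataclass
class ReadReport:
    """QC tally returned alongside parsed resightings."""

    n_read: int = 0
    n_kept: int = 0
    n_rejected_unknown_collar: int = 0


class RecordError(ValueError):
    """Row-level validation error carrying the 1-based data row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def _parse_date(value: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise RecordError(row, f"malformed date {value!r} (expected ISO-8601)") from None


def read_resightings(path, registry) -> tuple[list, ReadReport]:
    """Read ``resightings.csv`` (bird_id, date, region).

    Collar codes are uppercased on ingest, then matched case-sensitively
    against ``registry`` (a set of valid codes); rows whose code is absent —
    obvious collar misreadings — are dropped and tallied in the report.
    Malformed dates or unknown region codes raise :class:`RecordError`
    naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"bird_id", "date", "region"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if len(df) == 0:
        raise ValueError(f"{path}: no resighting records")
    registry = set(registry)
    out: list[Resighting] = []
    report = ReadReport(n_read=len(df))
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        bird_id = str(rec.bird_id).strip().upper()
        if not bird_id:
            raise RecordError(i, "empty bird_id")
        if bird_id not in registry:
            report.n_rejected_unknown_collar += 1
            continue
        date = _parse_date(rec.date, i)
        try:
            region = Region.from_code(str(rec.region))
        except ValueError as e:
            raise RecordError(i, str(e)) from None
        out.append(Resighting(bird_id=bird_id, date=date, region=region))
    report.n_kept = len(out)
    return out, report


def write_resightings(resightings: Iterable[Resighting], path) -> None:
    rows = [
        {"bird_id": r.bird_id, "date": r.date.isoformat(), "region": r.region.name}
        for r in resightings
    ]
    pd.DataFrame(rows, columns=["bird_id", "date", "region"]).to_csv(path, index=False)


_MISSING = {"", "NA", "NaN", "nan", "None"}


def read_birds(path) -> dict[str, Bird]:
    """Read ``birds.csv`` into a registry keyed by collar code.

    Schema: bird_id, ring_date, sex, age_at_ringing, pair_id (optional) plus
    optional wide columns ``brood_<year>`` in {0,1,NA} giving per-season
    breeding status.  "NA"/empty means missing throughout.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"bird_id", "ring_date", "sex", "age_at_ringing"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    brood_cols = {c: int(c.split("_", 1)[1]) for c in df.columns if c.startswith("brood_")}
    birds: dict[str, Bird] = {}
    for i, rec in enumerate(df.to_dict("records"), start=1):
        bird_id = str(rec["bird_id"]).strip().upper()
        if not bird_id:
            raise RecordError(i, "empty bird_id")
        if bird_id in birds:
            raise RecordError(i, f"duplicate bird_id {bird_id!r}")
        pair = str(rec.get("pair_id", "")).strip()
        status = {}
        for col, year in brood_cols.items():
            v = str(rec[col]).strip()
            if v in _MISSING:
                continue
            status[year] = "brood" if v in ("1", "brood") else "no_brood"
        birds[bird_id] = Bird(
            bird_id=bird_id,
            ring_date=_parse_date(rec["ring_date"], i),
            sex=str(rec["sex"]).strip().upper(),
            age_at_ringing=str(rec["age_at_ringing"]).strip(),
            pair_id=pair if pair not in _MISSING else None,
            breeding_status=status,
        )
    return birds


def write_birds(birds: Iterable[Bird], path) -> None:
    birds = list(birds)
    years = sorted({y for b in birds for y in b.breeding_status})
    rows = []
    for b in birds:
        row = {
            "bird_id": b.bird_id,
            "ring_date": b.ring_date.isoformat(),
            "sex": b.sex,
            "age_at_ringing": b.age_at_ringing,
            "pair_id": b.pair_id or "NA",
        }
        for y in years:
            s = b.breeding_status.get(y)
            row[f"brood_{y}"] = "NA" if s is None else ("1" if s == "brood" else "0")
        rows.append(row)
    cols = ["bird_id", "ring_date", "sex", "age_at_ringing", "pair_id"] + [
        f"brood_{y}" for y in years
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read the annual covariate table (year, harvest_rate, temp_<REG>,
    <crop>_<REG> areas, arable_<REG>_old/new); "NA"/empty parse as NaN."""
    df = pd.read_csv(path, na_values=sorted(_MISSING), keep_default_na=True)
    if "year" not in df.columns:
        raise ValueError(f"{path}: missing 'year' column")
    df["year"] = df["year"].astype(int)
    return df.set_index("year", drop=False)
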