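"""Strategy classification from resighting streams and change-event tables.

The core classification step: for every bird and season, the set of regions
with at least one in-window sighting is the bird's wintering strategy for
that season.  A bird's ringing season is excluded (its data are incomplete
because marking happens at the end of that winter), as are configured
low-sample seasons (by default the first, 1990).  Consecutive-season pairs
of assigned strategies yield change events.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import (
    DEFAULT_WINDOW,
    STRATEGY_BY_LABEL,
    Bird,
    Resighting,
    SeasonYear,
    Strategy,
    WinterWindow,
    in_wintering_window,
    season_of,
)

__all__ = [
    "StrategyTable",
    "ChangeEvent",
    "assign_strategies",
    "change_events",
    "successive_pairs",
    "dedupe_pairs_for_breeding",
]


class StrategyTable(dict):
    """Mapping (bird_id, season start year) → :class:`Strategy`.

    Bird-seasons with zero in-window sightings are simply absent — missing
    data, never an empty region set.
    """

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bird_id": b, "season": y, "strategy": s.label}
            for (b, y), s in sorted(self.items())
        ]
        return pd.DataFrame(rows, columns=["bird_id", "season", "strategy"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StrategyTable":
        table = cls()
        for rec in df.itertuples(index=False):
            table[(str(rec.bird_id), int(rec.season))] = STRATEGY_BY_LABEL[str(rec.strategy)]
        return table


@dataclass(frozen=True)
class ChangeEvent:
    """One year-on-year observation pair for a bird.

    ``changed`` is True iff the region subsets differ between the two
    consecutive seasons.  ``sexage_group`` classifies the bird at the
    arrival season: third-winter males/females (M3/F3, known-age birds
    only) versus adults (Mad/Fad).  ``breeding_transition`` says whether
    the bird's breeding status was the same or different across the pair
    ("unknown" when either season's status is missing).
    """

    bird_id: str
    season_t: int
    strategy_t: Strategy
    strategy_t1: Strategy
    changed: bool
    sexage_group: str
    breeding_transition: str = "unknown"

    def __post_init__(self):
        if self.changed != (self.strategy_t != self.strategy_t1):
            raise ValueError("changed flag inconsistent with strategies")


def assign_strategies(
    resightings: list,
    birds: dict,
    window: WinterWindow = DEFAULT_WINDOW,
    excluded_seasons: tuple = (1990,),
) -> StrategyTable:
    """Build the bird × season strategy table.

    Only in-window sightings count; each bird-season's strategy is the set
    of regions seen at least once (a single sighting establishes regional
    presence).  Ringing-season entries and ``excluded_seasons`` are
    removed.  Sightings of birds absent from the registry are ignored.
    """
    excluded = set(excluded_seasons)
    regions_used: dict[tuple[str, int], set] = {}
    for r in resightings:
        if r.bird_id not in birds:
            continue
        if not in_wintering_window(r.date, window):
            continue
        year = season_of(r.date).start_year
        if year in excluded:
            continue
        if year <= birds[r.bird_id].ring_season.start_year:
            continue
        regions_used.setdefault((r.bird_id, year), set()).add(r.region)
    table = StrategyTable()
    for key, regions in regions_used.items():
        table[key] = Strategy.from_regions(regions)
    return table


def _breeding_transition(bird: Bird, year_t: int) -> str:
    a = bird.breeding_status.get(year_t)
    b = bird.breeding_status.get(year_t + 1)
    if a is None or b is None:
        return "unknown"
    return "same" if a == b else "different"


def _sexage_group(bird: Bird, season_t1: int) -> str:
    # third winter applies only to known-age (first-winter-ringed) birds
    if bird.age_at_ringing == "first_winter":
        winter_no = season_t1 - bird.ring_season.start_year + 1
        if winter_no == 3:
            return "M3" if bird.sex == "M" else "F3"
    return "Mad" if bird.sex == "M" else "Fad"


def change_events(table: StrategyTable, birds: dict) -> list:
    """All year-on-year strategy pairs per bird.

    A gap (missing season) produces no event: events require strategies in
    two strictly consecutive seasons.
    """
    by_bird: dict[str, list[int]] = {}
    for bird_id, year in table:
        by_bird.setdefault(bird_id, []).append(year)
    events: list[ChangeEvent] = []
    for bird_id in sorted(by_bird):
        bird = birds[bird_id]
        for year in sorted(by_bird[bird_id]):
            if (bird_id, year + 1) not in table:
                continue
            s_t = table[(bird_id, year)]
            s_t1 = table[(bird_id, year + 1)]
            events.append(
                ChangeEvent(
                    bird_id=bird_id,
                    season_t=year,
                    strategy_t=s_t,
                    strategy_t1=s_t1,
                    changed=s_t != s_t1,
                    sexage_group=_sexage_group(bird, year + 1),
                    breeding_transition=_breeding_transition(bird, year),
                )
            )
    return events


def successive_pairs(events: list) -> tuple[list, int]:
    """Immediately successive event pairs per bird.

    Returns ``(pairs, n_birds)`` where each pair is ``(event_t, event_t1)``
    with ``event_t1.season_t == event_t.season_t + 1`` (i.e. data from
    three consecutive seasons), and ``n_birds`` counts distinct birds
    contributing at least one pair.
    """
    by_bird: dict[str, dict[int, ChangeEvent]] = {}
    for e in events:
        by_bird.setdefault(e.bird_id, {})[e.season_t] = e
    pairs = []
    birds_with_pairs = set()
    for bird_id in sorted(by_bird):
        seasons = by_bird[bird_id]
        for year in sorted(seasons):
            if year + 1 in seasons:
                pairs.append((seasons[year], seasons[year + 1]))
                birds_with_pairs.add(bird_id)
    return pairs, len(birds_with_pairs)


def dedupe_pairs_for_breeding(events: list, birds: dict) -> list:
    """Keep one member per pair to avoid pseudoreplication.

    For each pair identifier the lexicographically smallest bird_id is
    retained; unpaired birds (pair_id missing) are always kept.
    """
    keeper: dict[str, str] = {}
    for e in events:
        bird = birds.get(e.bird_id)
        if bird is None or bird.pair_id is None:
            continue
        cur = keeper.get(bird.pair_id)
        if cur is None or e.bird_id < cur:
            keeper[bird.pair_id] = e.bird_id
    out = []
    for e in events:
        pid = birds[e.bird_id].pair_id if e.bird_id in birds else None
        if pid is None or keeper[pid] == e.bird_id:
            out.append(e)
    return out


def events_to_frame(events: list) -> pd.DataFrame:
    rows = [
        {
            "bird_id": e.bird_id,
            "season_t": e.season_t,
            "strategy_t": e.strategy_t.label,
            "strategy_t1": e.strategy_t1.label,
            "changed": int(e.changed),
            "sexage_group": e.sexage_group,
            "breeding_transition": e.breeding_transition,
        }
        for e in events
    ]
    cols = [
        "bird_id", "season_t", "strategy_t", "strategy_t1",
        "changed", "sexage_group", "breeding_transition",
    ]
    return pd.DataFrame(rows, columns=cols)


def events_from_frame(df: pd.DataFrame) -> list:
    return [
        ChangeEvent(
            bird_id=str(r.bird_id),
            season_t=int(r.season_t),
            strategy_t=STRATEGY_BY_LABEL[str(r.strategy_t)],
            strategy_t1=STRATEGY_BY_LABEL[str(r.strategy_t1)],
            changed=bool(r.changed),
            sexage_group=str(r.sexage_group),
            breeding_transition=str(r.breeding_transition),
        )
        for r in df.itertuples(index=False)
    ]
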