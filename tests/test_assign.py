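"""Strategy classification and change-event derivation."""

import datetime as dt

import pytest

from pinkfoot.assign import (
    StrategyTable,
    assign_strategies,
    change_events,
    dedupe_pairs_for_breeding,
    successive_pairs,
)
from pinkfoot.core import Bird, Region, Resighting, Strategy


def _bird(bid, ring_year=1994, sex="M", age="older", pair=None, status=None):
    return Bird(
        bird_id=bid,
        ring_date=dt.date(ring_year + 1, 4, 1),  # spring capture: ring season = ring_year
        sex=sex,
        age_at_ringing=age,
        pair_id=pair,
        breeding_status=status or {},
    )


def _sight(bid, y, m, d, region):
    return Resighting(bird_id=bid, date=dt.date(y, m, d), region=region)


class TestAssignStrategies:
    def test_region_set_maps_to_strategy(self):
        birds = {"A1": _bird("A1")}
        rs = [_sight("A1", 1995, 10, 5, Region.JU), _sight("A1", 1996, 1, 10, Region.FR)]
        table = assign_strategies(rs, birds, excluded_seasons=())
        assert table[("A1", 1995)].label == "Ju-Fr"

    def test_ringing_season_excluded_even_if_sighted(self):
        birds = {"A1": _bird("A1", ring_year=1991)}
        rs = [
            _sight("A1", 1992, 2, 1, Region.JU),  # 1991/92 = ringing season
            _sight("A1", 1992, 11, 1, Region.JU),
        ]
        table = assign_strategies(rs, birds, excluded_seasons=())
        assert ("A1", 1991) not in table
        assert table[("A1", 1992)].label == "Ju"

    def test_configured_seasons_removed(self):
        birds = {"A1": _bird("A1", ring_year=1988)}
        rs = [_sight("A1", 1990, 10, 1, Region.JU), _sight("A1", 1991, 10, 1, Region.JU)]
        table = assign_strategies(rs, birds, excluded_seasons=(1990,))
        assert ("A1", 1990) not in table and ("A1", 1991) in table

    def test_out_of_window_sightings_ignored(self):
        birds = {"A1": _bird("A1")}
        rs = [
            _sight("A1", 1996, 10, 1, Region.JU),
            _sight("A1", 1996, 7, 15, Region.FL),  # summer: outside the window
        ]
        table = assign_strategies(rs, birds, excluded_seasons=())
        assert table[("A1", 1996)].label == "Ju"

    def test_missing_means_absent_not_empty(self):
        birds = {"A1": _bird("A1")}
        table = assign_strategies([], birds, excluded_seasons=())
        assert len(table) == 0
        for strategy in table.values():  # pragma: no cover - vacuous
            assert strategy.regions


class TestChangeEvents:
    def _table(self, entries):
        t = StrategyTable()
        for bid, year, label in entries:
            t[(bid, year)] = Strategy.from_label(label)
        return t

    def test_no_change_flag(self):
        birds = {"A1": _bird("A1")}
        t = self._table([("A1", 1995, "Ju-Fr"), ("A1", 1996, "Ju-Fr")])
        (e,) = change_events(t, birds)
        assert e.changed is False and e.season_t == 1995

    def test_change_flag(self):
        birds = {"A1": _bird("A1")}
        t = self._table([("A1", 1995, "Ju-Fr"), ("A1", 1996, "Ju-Fr-Fl")])
        (e,) = change_events(t, birds)
        assert e.changed is True

    def test_gap_produces_no_event(self):
        birds = {"A1": _bird("A1")}
        t = self._table([("A1", 1995, "Ju"), ("A1", 1997, "Fr")])
        assert change_events(t, birds) == []

    def test_third_winter_group_for_known_age(self):
        # ringed first winter 1994 -> third winter is 1996; the 1995->1996
        # event is the first acknowledgeable change
        birds = {"A1": _bird("A1", ring_year=1994, sex="M", age="first_winter")}
        t = self._table([("A1", 1995, "Ju"), ("A1", 1996, "Fr"), ("A1", 1997, "Fr")])
        e1, e2 = change_events(t, birds)
        assert e1.sexage_group == "M3"
        assert e2.sexage_group == "Mad"

    def test_older_ringed_never_third_winter(self):
        birds = {"A1": _bird("A1", ring_year=1994, sex="F", age="older")}
        t = self._table([("A1", 1995, "Ju"), ("A1", 1996, "Fr")])
        (e,) = change_events(t, birds)
        assert e.sexage_group == "Fad"

    def test_breeding_transition_levels(self):
        status = {1995: "brood", 1996: "brood", 1997: "no_brood"}
        birds = {"A1": _bird("A1", status=status)}
        t = self._table(
            [("A1", 1995, "Ju"), ("A1", 1996, "Ju"), ("A1", 1997, "Ju"), ("A1", 1998, "Ju")]
        )
        e1, e2, e3 = change_events(t, birds)
        assert e1.breeding_transition == "same"
        assert e2.breeding_transition == "different"
        assert e3.breeding_transition == "unknown"

    def test_event_count_bound(self, small_dataset):
        cfg, birds, resightings, _, _ = small_dataset
        table = assign_strategies(resightings, birds, window=cfg.window, excluded_seasons=())
        events = change_events(table, birds)
        n_birds = len({b for b, _ in table})
        assert len(events) <= len(table) - n_birds


class TestSuccessivePairs:
    def _events(self, birds, entries):
        t = StrategyTable()
        for bid, year, label in entries:
            t[(bid, year)] = Strategy.from_label(label)
        return change_events(t, birds)

    def test_consecutive_events_pair(self):
        birds = {"A1": _bird("A1")}
        ev = self._events(
            birds, [("A1", 1995, "Ju"), ("A1", 1996, "Fr"), ("A1", 1997, "Ju")]
        )
        pairs, n = successive_pairs(ev)
        assert len(pairs) == 1 and n == 1
        (a, b) = pairs[0]
        assert a.season_t == 1995 and b.season_t == 1996

    def test_nonconsecutive_events_do_not_pair(self):
        birds = {"A1": _bird("A1")}
        # events exist for 1995->1996 and 1998->1999 but not 1996->1997,
        # so no three consecutive seasons anywhere: zero pairs
        ev = self._events(
            birds,
            [("A1", 1995, "Ju"), ("A1", 1996, "Fr"), ("A1", 1998, "Ju"), ("A1", 1999, "Fr")],
        )
        pairs, _ = successive_pairs(ev)
        assert pairs == []

    def test_pair_count_matches_bruteforce(self, small_dataset):
        cfg, birds, resightings, _, _ = small_dataset
        table = assign_strategies(resightings, birds, window=cfg.window, excluded_seasons=())
        events = change_events(table, birds)
        pairs, _ = successive_pairs(events)
        # brute force: scan all triples of consecutive seasons per bird
        by_bird = {}
        for (b, y) in table:
            by_bird.setdefault(b, set()).add(y)
        expected = sum(
            1
            for b, ys in by_bird.items()
            for y in ys
            if y + 1 in ys and y + 2 in ys
        )
        assert len(pairs) == expected


class TestDedupe:
    def test_smallest_id_kept_per_pair(self):
        birds = {
            "A01": _bird("A01", pair="P1"),
            "B02": _bird("B02", pair="P1", sex="F"),
        }
        t = StrategyTable()
        for bid in birds:
            t[(bid, 1995)] = Strategy.from_label("Ju")
            t[(bid, 1996)] = Strategy.from_label("Fr")
        ev = change_events(t, birds)
        kept = dedupe_pairs_for_breeding(ev, birds)
        assert {e.bird_id for e in kept} == {"A01"}

    def test_unpaired_always_kept(self):
        birds = {"A01": _bird("A01")}
        t = StrategyTable()
        t[("A01", 1995)] = Strategy.from_label("Ju")
        t[("A01", 1996)] = Strategy.from_label("Ju")
        ev = change_events(t, birds)
        assert dedupe_pairs_for_breeding(ev, birds) == ev

    def test_counting_pairs_plus_singletons(self, small_dataset):
        cfg, birds, resightings, _, _ = small_dataset
        table = assign_strategies(resightings, birds, window=cfg.window, excluded_seasons=())
        events = change_events(table, birds)
        kept = dedupe_pairs_for_breeding(events, birds)
        kept_birds = {e.bird_id for e in kept}
        event_birds = {e.bird_id for e in events}
        pair_ids = {birds[b].pair_id for b in event_birds if birds[b].pair_id}
        singletons = {b for b in event_birds if birds[b].pair_id is None}
        # exactly one representative per pair with events, plus all singletons
        assert len(kept_birds) == len(pair_ids) + len(singletons)
        assert singletons <= kept_birds
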