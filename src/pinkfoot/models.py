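"""The four strategy-switching models.

Each wrapper builds the appropriate fixed/random structure over change
events and returns a :class:`~pinkfoot.glmm.GlmmFit`:

* year trend:       changed ~ year            + (1 | bird)
* sex/age groups:   changed ~ group           + (1 | bird) + (1 | year)
* breeding status:  changed ~ same/different  + (1 | bird) + (1 | year)
* previous choice:  changed(t+1) ~ changed(t) + (1 | bird) + (1 | year)

Year always refers to the starting year of the departure season of a
change event.  The population size is deliberately never a covariate: over
the study period it is nearly collinear with year (the two are causally
inseparable), so the year effect absorbs both behavioural change and any
density dependence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .assign import events_to_frame, successive_pairs
from .glmm import GlmmFit, GlmmSpec, fit_glmm

__all__ = [
    "model_change_by_year",
    "model_change_by_sexage",
    "model_change_by_breeding",
    "model_change_by_previous",
]


def model_change_by_year(events, nagq: int = 1) -> GlmmFit:
    """Annual change probability against year, bird as random intercept.

    Adds ``fit.predictions`` with the population-level change probability
    (and 95% CI) at the first and last event year.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    df = df.rename(columns={"season_t": "year"})
    spec = GlmmSpec(response="changed", fixed=("year",), random=("bird_id",))
    fit = fit_glmm(df, spec, nagq=nagq)
    center = fit.offsets.get("year", 0.0)
    rows = []
    for year in (int(df["year"].min()), int(df["year"].max())):
        x = np.array([1.0, year - center])
        p, lo, hi = fit.predict_prob(x)
        rows.append({"year": year, "prob": p, "lo": lo, "hi": hi})
    fit.predictions = pd.DataFrame(rows)
    return fit


_GROUPS = ("F3", "M3", "Fad", "Mad")


def model_change_by_sexage(events) -> tuple[GlmmFit, pd.DataFrame]:
    """Change probability per sex/age group, with the two within-age sex
    contrasts (3rd-winter M vs F; adult M vs F).

    Returns ``(fit, contrasts)``; ``fit.predictions`` holds per-group
    probabilities with 95% CIs.  A contrast is skipped with a warning when
    one of its group levels is absent from the data.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    spec = GlmmSpec(
        response="changed", fixed=("sexage_group",), random=("bird_id", "season_t")
    )
    fit = fit_glmm(df, spec)
    present = set(df["sexage_group"].astype(str).unique())
    ref = sorted(present)[0]

    def term(level: str) -> dict:
        return {} if level == ref else {f"sexage_group[{level}]": 1.0}

    preds = []
    for g in _GROUPS:
        if g not in present:
            continue
        x = np.zeros(len(fit.params))
        x[0] = 1.0
        for t, w in term(g).items():
            x[list(fit.params.index).index(t)] = w
        p, lo, hi = fit.predict_prob(x)
        preds.append({"group": g, "prob": p, "lo": lo, "hi": hi})
    fit.predictions = pd.DataFrame(preds)

    rows = []
    for a, b, label in (("M3", "F3", "3rd winter M vs F"), ("Mad", "Fad", "adult M vs F")):
        if a not in present or b not in present:
            warnings.warn(f"group level missing; skipping contrast {label}", RuntimeWarning)
            continue
        c = fit.contrast(term(a), term(b))
        c["contrast"] = label
        rows.append(c)
    contrasts = pd.DataFrame(rows)
    return fit, contrasts


def model_change_by_breeding(deduped_events) -> GlmmFit:
    """Change probability against breeding-status transition (same vs
    different status in the two consecutive seasons).

    Input must already be pair-deduplicated (one bird per pair) to avoid
    pseudoreplication; events with unknown status in either season are
    excluded.
    """
    df = (
        deduped_events
        if isinstance(deduped_events, pd.DataFrame)
        else events_to_frame(deduped_events)
    )
    df = df[df["breeding_transition"].isin(["same", "different"])]
    if len(df) == 0:
        raise ValueError("no events with known breeding status in both seasons")
    levels = set(df["breeding_transition"].unique())
    if len(levels) < 2:
        warnings.warn(
            f"only one breeding-transition level present ({levels}); "
            "the status effect is not estimable",
            RuntimeWarning,
        )
    spec = GlmmSpec(
        response="changed", fixed=("breeding_transition",), random=("bird_id", "season_t")
    )
    return fit_glmm(df, spec)


def model_change_by_previous(events) -> GlmmFit:
    """Did changing in year t make changing again in year t+1 more likely?

    Uses immediately successive event pairs (three consecutive seasons of
    data); the year-t change flag is the fixed effect, with bird and year
    random intercepts.  Between-bird heterogeneity in switching propensity
    shows up here as a positive year-t coefficient even without any
    explicit behavioural memory.
    """
    if not isinstance(events, list):
        from .assign import events_from_frame

        events = events_from_frame(events)
    pairs, n_birds = successive_pairs(events)
    if not pairs:
        raise ValueError(
            "no immediately successive event pairs: need data from three "
            "consecutive seasons for at least one bird"
        )
    df = pd.DataFrame(
        {
            "bird_id": [b.bird_id for _, b in pairs],
            "season_t": [b.season_t for _, b in pairs],
            "changed": [int(b.changed) for _, b in pairs],
            "prev_changed": [int(a.changed) for a, _ in pairs],
        }
    )
    spec = GlmmSpec(
        response="changed", fixed=("prev_changed",), random=("bird_id", "season_t")
    )
    fit = fit_glmm(df, spec)
    fit.n_groups["birds_with_pairs"] = n_birds
    return fit
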