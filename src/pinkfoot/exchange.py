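"""Directional net exchange between wintering strategies per period.

For a set of change events inside a period, the net flow from strategy a
to strategy b is the difference of opposing change counts expressed as a
proportion of all changes in the period:

    net(a, b) = (c(a→b) − c(b→a)) / total changes.

The matrix is antisymmetric with zero diagonal, and the sum of |net| over
unordered pairs is at most 1 (equal to 1 exactly when no pair has
opposing flows).  Small flows below 2.5% of all changes are conventionally
filtered out for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import STRATEGIES

__all__ = ["NetExchangeMatrix", "net_exchange", "filter_small_flows"]

_INDEX = {s: i for i, s in enumerate(STRATEGIES)}
_LABELS = [s.label for s in STRATEGIES]


@dataclass
class NetExchangeMatrix:
    """7×7 antisymmetric net-flow matrix for one period."""

    period: tuple  # inclusive (first_year, last_year)
    flow: np.ndarray  # (7, 7); flow[a, b] > 0 means net movement a → b
    total_changes: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(_LABELS):
            for j, b in enumerate(_LABELS):
                if i < j and self.flow[i, j] != 0.0:
                    src, dst = (a, b) if self.flow[i, j] > 0 else (b, a)
                    rows.append(
                        {"from": src, "to": dst, "net_proportion": abs(float(self.flow[i, j]))}
                    )
        return pd.DataFrame(rows, columns=["from", "to", "net_proportion"])


def net_exchange(events, period: tuple) -> NetExchangeMatrix:
    """Net-exchange matrix over change events whose departure season
    (season_t) lies inside the inclusive ``period``."""
    lo, hi = period
    counts = np.zeros((len(STRATEGIES), len(STRATEGIES)))
    total = 0
    for e in events:
        if not (lo <= e.season_t <= hi) or not e.changed:
            continue
        counts[_INDEX[e.strategy_t], _INDEX[e.strategy_t1]] += 1
        total += 1
    if total == 0:
        warnings.warn(f"no strategy changes in period {lo}-{hi}; zero matrix")
        return NetExchangeMatrix(period=period, flow=counts, total_changes=0)
    flow = (counts - counts.T) / total
    return NetExchangeMatrix(period=period, flow=flow, total_changes=total)


def filter_small_flows(matrix: NetExchangeMatrix, threshold: float = 0.025) -> NetExchangeMatrix:
    """Zero entries with |net| strictly below ``threshold`` (flows at
    exactly the threshold are kept); antisymmetry is preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    flow = np.where(np.abs(matrix.flow) < threshold, 0.0, matrix.flow)
    return NetExchangeMatrix(
        period=matrix.period, flow=flow, total_changes=matrix.total_changes
    )
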