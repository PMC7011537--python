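"""Consensus analysis: per-goal top-category proportions and threshold sweeps.

A goal "reaches consensus" when at least a threshold share of the panel
rates it in the top category ("main goal").  Because the choice of
threshold is itself a study parameter, the summary counts how many goals
clear each threshold in a configurable sweep (default 60/70/75/80/90%).
Proportions are compared unrounded; rounding to one decimal is applied
only for display.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import RatingsPanel
from .scales import RatingScale, is_top_category

__all__ = [
    "Rule",
    "ConsensusTable",
    "ThresholdSummary",
    "EmptyCellError",
    "DEFAULT_THRESHOLDS",
    "reached_consensus",
    "top_proportion",
    "consensus_table",
    "threshold_counts",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (60.0, 70.0, 75.0, 80.0, 90.0)


class Rule(str, enum.Enum):
    """Threshold comparison rule: inclusive (>=) or strict (>)."""

    AT_LEAST = "at_least"
    STRICT = "strict"


class EmptyCellError(ValueError):
    """No ratings exist for a requested (goal, scale, round) cell.

    Distinct from a genuine 0% proportion, which requires a populated cell.
    """


def reached_consensus(proportion: float, threshold: float, rule: Rule = Rule.AT_LEAST) -> bool:
    """Single-cell consensus predicate, consistent with :func:`threshold_counts`."""
    if rule is Rule.AT_LEAST:
        return proportion >= threshold
    return proportion > threshold


@dataclass(frozen=True)
class ConsensusTable:
    """Per-goal top-category percentages for one survey round.

    ``cells`` is a goals x scales DataFrame of percentages in [0, 100];
    ``denominators`` holds the participant count behind each cell.
    """

    round: int
    cells: pd.DataFrame
    denominators: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.cells.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("consensus proportions must lie in [0, 100]")
        if np.any(self.denominators.to_numpy() < 1):
            raise ValueError("every populated cell needs denominator >= 1")

    @classmethod
    def from_percentages(
        cls, cells: pd.DataFrame, round: int, denominators: pd.DataFrame | None = None
    ) -> "ConsensusTable":
        """Build a table directly from a goals x scales percentage grid.

        Used for externally published grids where only the percentages
        (not the raw ratings) are available; denominators default to 1.
        """
        if denominators is None:
            denominators = pd.DataFrame(1, index=cells.index, columns=cells.columns)
        return cls(round=round, cells=cells.astype(float), denominators=denominators)

    def display(self) -> pd.DataFrame:
        """Percentages rounded to one decimal, for human-readable output."""
        return self.cells.round(1)


@dataclass(frozen=True)
class ThresholdSummary:
    """Number of goals reaching each threshold, per scale, for one round."""

    round: int
    rule: Rule
    thresholds: tuple[float, ...]
    counts: pd.DataFrame  # thresholds x scales, integer counts
    total_goals: int

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if np.any((c < 0) | (c > self.total_goals)):
            raise ValueError("counts must lie in [0, total_goals]")
        if np.any(np.diff(c, axis=0) > 0):
            raise ValueError("counts must be non-increasing in the threshold")

    def percentages(self) -> pd.DataFrame:
        """Counts expressed as a percentage of the goal list."""
        return 100.0 * self.counts / self.total_goals


def top_proportion(panel: RatingsPanel, goal: str, scale_id: str, round: int) -> float:
    """Percentage of participants rating ``goal`` in the top category.

    The top category is membership of the harmonized MAIN level, so five-
    and nine-point cells are automatically on their starred (collapsed)
    scale.  Raises :class:`EmptyCellError` when the cell has no ratings.
    """
    scale = panel.scales[scale_id]
    df = panel.frame
    cell = df[(df["goal_id"] == goal) & (df["scale_id"] == scale_id) & (df["round"] == round)]
    if cell.empty:
        raise EmptyCellError(f"no ratings for goal={goal!r} scale={scale_id!r} round={round}")
    top = cell["rating"].map(lambda r: is_top_category(scale, r))
    return 100.0 * float(top.sum()) / float(len(cell))


def consensus_table(panel: RatingsPanel, round: int) -> ConsensusTable:
    """Goals x scales table of top-category percentages for one round.

    Covers every registered scale the round has any ratings for; a scale
    present in the round but missing for some goal raises
    :class:`EmptyCellError` listing the affected cells.
    """
    df = panel.frame
    sub = df[df["round"] == round]
    if sub.empty:
        raise EmptyCellError(f"no ratings at all in round {round}")
    observed = set(sub["scale_id"])
    scale_ids = [sid for sid in panel.scales if sid in observed]
    cells = pd.DataFrame(index=list(panel.goals), columns=scale_ids, dtype=float)
    denom = pd.DataFrame(index=list(panel.goals), columns=scale_ids, dtype=int)
    empty: list[tuple[str, str]] = []
    top_flag = {
        sid: {c: is_top_category(panel.scales[sid], c) for c in panel.scales[sid].categories}
        for sid in scale_ids
    }
    sub = sub.assign(
        is_top=[top_flag[s][r] for s, r in zip(sub["scale_id"], sub["rating"])]
    )
    agg = sub.groupby(["goal_id", "scale_id"], sort=False)["is_top"].agg(n="size", n_top="sum")
    for goal in panel.goals:
        for sid in scale_ids:
            try:
                row = agg.loc[(goal, sid)]
            except KeyError:
                empty.append((goal, sid))
                continue
            cells.at[goal, sid] = 100.0 * row["n_top"] / row["n"]
            denom.at[goal, sid] = row["n"]
    if empty:
        raise EmptyCellError(f"no ratings in round {round} for cells: {empty[:10]}")
    return ConsensusTable(round=round, cells=cells, denominators=denom.astype(int))


def threshold_counts(
    table: ConsensusTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    rule: Rule = Rule.AT_LEAST,
) -> ThresholdSummary:
    """Count goals reaching each threshold, per scale, using unrounded cells."""
    thresholds = tuple(float(t) for t in thresholds)
    if any(not (0.0 < t <= 100.0) for t in thresholds):
        raise ValueError(f"thresholds must lie in (0, 100], got {thresholds}")
    thresholds = tuple(sorted(thresholds))
    vals = table.cells
    rows = {}
    for t in thresholds:
        if rule is Rule.AT_LEAST:
            rows[t] = (vals >= t).sum(axis=0)
        else:
            rows[t] = (vals > t).sum(axis=0)
    counts = pd.DataFrame(rows).T.astype(int)
    counts.index.name = "threshold"
    return ThresholdSummary(
        round=table.round,
        rule=rule,
        thresholds=thresholds,
        counts=counts,
        total_goals=len(table.cells.index),
    )
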