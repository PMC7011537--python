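"""Rating panels: the participant x round x goal x scale data model.

A panel holds one ordinal rating per (participant, round, goal, scale)
key.  Missing ratings are simply absent rows — there are no sentinel
values — which is what makes complete-case filtering well defined.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .scales import RatingScale, ScaleRegistry, builtin_scales

__all__ = [
    "DEFAULT_GOALS",
    "RatingRecord",
    "RatingsPanel",
    "PanelValidationError",
    "read_ratings_csv",
    "write_ratings_csv",
    "complete_case_filter",
    "validate_panel",
]

#: The 19 treatment-goal domains used in the knee-arthroplasty survey that
#: motivates this package.  Callers may supply their own goal list.
DEFAULT_GOALS: tuple[str, ...] = (
    "pain",
    "range_of_motion",
    "strength",
    "stability",
    "malalignment",
    "physical_function",
    "walking_distance",
    "walking_stairs",
    "activities_of_daily_living",
    "employability",
    "physical_activity",
    "sex_life",
    "quality_of_life",
    "global_health_status",
    "participation_in_social_life",
    "implant_survival",
    "no_side_effects",
    "duration_of_hospitalization",
    "preventing_secondary_impairments",
)

CSV_COLUMNS = ("participant_id", "round", "goal_id", "scale_id", "rating")


class PanelValidationError(ValueError):
    """A panel violates its structural invariants."""


@dataclass(frozen=True)
class RatingRecord:
    """One ordinal rating of one goal by one participant in one survey round."""

    participant_id: str
    round: int
    goal_id: str
    scale_id: str
    rating: str


class RatingsPanel:
    """Validated collection of ratings, backed by a long-format DataFrame.

    Parameters
    ----------
    frame:
        Columns ``participant_id, round, goal_id, scale_id, rating``; one
        row per rating, row order preserved.
    scales:
        Registry resolving every ``scale_id`` in the frame.
    goals:
        Ordered goal labels; every ``goal_id`` must be listed.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        scales: ScaleRegistry | None = None,
        goals: Sequence[str] | None = None,
        *,
        check: bool = True,
    ) -> None:
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise PanelValidationError(f"panel frame lacks columns {missing}")
        df = frame.loc[:, list(CSV_COLUMNS)].reset_index(drop=True)
        df["participant_id"] = df["participant_id"].astype(str)
        df["round"] = df["round"].astype(int)
        df["goal_id"] = df["goal_id"].astype(str)
        df["scale_id"] = df["scale_id"].astype(str)
        df["rating"] = df["rating"].astype(str)
        self._df = df
        self.scales = scales if scales is not None else builtin_scales()
        self.goals = tuple(goals) if goals is not None else DEFAULT_GOALS
        if check:
            issues = self.validate()
            if issues:
                raise PanelValidationError("; ".join(issues[:5]) + ("" if len(issues) <= 5 else f" (+{len(issues) - 5} more)"))

    @classmethod
    def from_records(
        cls,
        records: Iterable[RatingRecord | tuple],
        scales: ScaleRegistry | None = None,
        goals: Sequence[str] | None = None,
        *,
        check: bool = True,
    ) -> "RatingsPanel":
        rows = [
            (r.participant_id, r.round, r.goal_id, r.scale_id, r.rating)
            if isinstance(r, RatingRecord)
            else tuple(r)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        return cls(frame, scales=scales, goals=goals, check=check)

    # -- views ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying long-format frame."""
        return self._df.copy()

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying frame (do not mutate)."""
        return self._df

    def records(self) -> Iterator[RatingRecord]:
        for row in self._df.itertuples(index=False):
            yield RatingRecord(row.participant_id, row.round, row.goal_id, row.scale_id, row.rating)

    def participants(self) -> tuple[str, ...]:
        return tuple(sorted(self._df["participant_id"].unique()))

    @property
    def n_participants(self) -> int:
        return self._df["participant_id"].nunique()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingsPanel):
            return NotImplemented
        return self._df.equals(other._df) and self.goals == other.goals

    # -- validation ----------------------------------------------------

    def validate(self) -> list[str]:
        """All invariant violations, as human-readable issue strings.

        An empty list means the panel is valid.
        """
        issues: list[str] = []
        df = self._df
        bad_round = df.index[~df["round"].isin((1, 2))]
        for i in bad_round:
            issues.append(f"record {i}: round {df.at[i, 'round']} not in {{1, 2}}")
        known_goals = set(self.goals)
        for i in df.index[~df["goal_id"].isin(known_goals)]:
            issues.append(f"record {i}: unregistered goal {df.at[i, 'goal_id']!r}")
        for scale_id, sub in df.groupby("scale_id", sort=False):
            if scale_id not in self.scales:
                issues.append(
                    f"records {list(sub.index[:3])}{'...' if len(sub) > 3 else ''}: unregistered scale {scale_id!r}"
                )
                continue
            scale = self.scales[scale_id]
            bad = sub.index[~sub["rating"].isin(scale.categories)]
            for i in bad:
                issues.append(
                    f"record {i}: rating {df.at[i, 'rating']!r} is not a category of scale {scale_id!r}"
                )
        dup = df.duplicated(subset=["participant_id", "round", "goal_id", "scale_id"], keep="first")
        for i in df.index[dup]:
            key = tuple(df.loc[i, ["participant_id", "round", "goal_id", "scale_id"]])
            issues.append(f"record {i}: duplicate key {key}")
        return issues


def read_ratings_csv(
    path: str | Path,
    scales: ScaleRegistry | None = None,
    goals: Sequence[str] | None = None,
) -> RatingsPanel:
    """Read a long-format ratings CSV into a validated panel.

    The file must be UTF-8, comma-separated, with a header naming the
    columns ``participant_id, round, goal_id, scale_id, rating``.  Row
    order is preserved.  Malformed rows raise a parse error naming the
    line; invariant violations (duplicate keys, ratings outside their
    scale, unregistered goals) raise :class:`PanelValidationError`.
    """
    path = Path(path)
    rows: list[tuple[str, int, str, str, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: header lacks columns {missing}")
        for rec in reader:
            line = reader.line_num
            if any(rec.get(c) in (None, "") for c in CSV_COLUMNS):
                raise ValueError(f"{path}:{line}: malformed row, empty or missing field")
            try:
                rnd = int(rec["round"])
            except ValueError:
                raise ValueError(f"{path}:{line}: round {rec['round']!r} is not an integer") from None
            rows.append((rec["participant_id"], rnd, rec["goal_id"], rec["scale_id"], rec["rating"]))
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    if goals is None:
        goals = tuple(dict.fromkeys(frame["goal_id"]))  # observed order
    return RatingsPanel(frame, scales=scales, goals=goals)


def write_ratings_csv(panel: RatingsPanel, path: str | Path) -> None:
    """Write a panel back to the standard five-column CSV."""
    panel.frame.to_csv(path, index=False)


def complete_case_filter(panel: RatingsPanel) -> RatingsPanel:
    """Drop participants without a full goals x scales grid in both rounds.

    Mirrors a complete-case analysis: a participant is retained only if
    every registered goal is rated on every registered scale in round 1
    and round 2.  Idempotent; never increases the participant count.
    """
    df = panel.frame
    expected = len(panel.goals) * len(panel.scales) * 2
    counts = df.groupby("participant_id")["rating"].size()
    complete = set(counts.index[counts == expected])
    kept = df[df["participant_id"].isin(complete)].reset_index(drop=True)
    return RatingsPanel(kept, scales=panel.scales, goals=panel.goals, check=False)


def validate_panel(panel: RatingsPanel) -> list[str]:
    """Functional alias for :meth:`RatingsPanel.validate`."""
    return panel.validate()
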