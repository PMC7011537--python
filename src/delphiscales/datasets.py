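"""Packaged reference data.

The package ships the goal-level top-category percentage grid published
by the motivating two-survey TKA treatment-goal study (19 goals x 3
scales x 2 rounds; five- and nine-point values are on the harmonized
top category, i.e. the starred scales).  The raw participant ratings of
that study were never deposited, so the grid is the only real-data input
available to downstream analyses such as the consensus threshold sweep.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consensus import ConsensusTable

__all__ = ["load_consensus_grid", "reference_consensus_tables"]


def load_consensus_grid() -> pd.DataFrame:
    """Long-format reference grid: goal_id, scale_id, round, top_pct."""
    ref = resources.files("delphiscales.data").joinpath("tka_consensus_grid.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["round"] = df["round"].astype(int)
    df["top_pct"] = df["top_pct"].astype(float)
    return df


def reference_consensus_tables() -> dict[int, ConsensusTable]:
    """The reference grid as one :class:`ConsensusTable` per round."""
    df = load_consensus_grid()
    out: dict[int, ConsensusTable] = {}
    for rnd, sub in df.groupby("round"):
        cells = sub.pivot(index="goal_id", columns="scale_id", values="top_pct")
        # keep file order for goals, fixed scale order for columns
        goal_order = sub["goal_id"].drop_duplicates().tolist()
        cells = cells.loc[goal_order, ["three_point", "five_point", "nine_point"]]
        out[int(rnd)] = ConsensusTable.from_percentages(cells, round=int(rnd))
    return out
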