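"""Cross-scale association within a survey round (Spearman's rho).

Two scales measuring the same construct should rank participants'
ratings similarly even when their granularity differs.  Ratings are
converted to integer codes via their scale's category order and
correlated with Spearman's rho (Pearson correlation of midranks), which
is invariant under strictly monotone recoding — exactly the property
needed to compare a three-level with a nine-level scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import RatingsPanel
from .scales import map_to_three

__all__ = [
    "CorrelationMatrix",
    "spearman_rho",
    "pairwise_scale_correlation",
    "interpret_correlation",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midranks for ties.

    Returns NaN (undefined) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric scale x scale Spearman matrix, optionally with per-goal detail.

    ``per_goal`` (when requested) is a long frame with columns
    goal_id, scale_a, scale_b, rho; undefined cells hold NaN.
    """

    round: int
    transformed: bool
    matrix: pd.DataFrame
    per_goal: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        finite = m[np.isfinite(m)]
        if np.any(np.abs(finite) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


def _coded_wide(panel: RatingsPanel, round: int, transformed: bool) -> pd.DataFrame:
    """participant x goal rows, one integer-coded column per scale."""
    df = panel.frame
    sub = df[df["round"] == round]
    codes = []
    for sid in panel.scales:
        scale = panel.scales[sid]
        if transformed:
            code = {c: int(map_to_three(scale, c)) for c in scale.categories}
        else:
            code = {c: i for i, c in enumerate(scale.categories)}
        s = sub[sub["scale_id"] == sid]
        codes.append(
            s.assign(code=s["rating"].map(code)).set_index(["participant_id", "goal_id"])["code"].rename(sid)
        )
    return pd.concat(codes, axis=1)


def pairwise_scale_correlation(
    panel: RatingsPanel,
    round: int,
    transformed: bool = False,
    per_goal: bool = False,
) -> CorrelationMatrix:
    """Spearman correlation between every pair of scales within one round.

    Each participant x goal rating is paired across the two scales; the
    pooled coefficient uses all goals together.  With ``transformed=True``
    ratings are first collapsed onto the three-level frame.  Cells with
    fewer than 2 complete pairs (or constant vectors) are NaN.
    """
    wide = _coded_wide(panel, round, transformed)
    sids = list(panel.scales)
    mat = pd.DataFrame(np.eye(len(sids)), index=sids, columns=sids)
    for a, b in itertools.combinations(sids, 2):
        pair = wide[[a, b]].dropna()
        rho = spearman_rho(pair[a], pair[b]) if len(pair) >= 2 else float("nan")
        mat.loc[a, b] = mat.loc[b, a] = rho
    detail = None
    if per_goal:
        rows = []
        present = set(wide.index.get_level_values("goal_id"))
        for goal in panel.goals:
            gw = (
                wide.xs(goal, level="goal_id", drop_level=True)
                if goal in present
                else wide.iloc[0:0].droplevel("goal_id")
            )
            for a, b in itertools.combinations(sids, 2):
                pair = gw[[a, b]].dropna()
                rho = spearman_rho(pair[a], pair[b]) if len(pair) >= 2 else float("nan")
                rows.append((goal, a, b, rho))
        detail = pd.DataFrame(rows, columns=["goal_id", "scale_a", "scale_b", "rho"])
    return CorrelationMatrix(round=round, transformed=transformed, matrix=mat, per_goal=detail)


#: Magnitude bands after Hinkle's rule of thumb; upper endpoints belong to
#: the lower band (except 1.0) so that labeling is deterministic.
_R_BANDS = (
    (0.30, "negligible"),
    (0.50, "low"),
    (0.70, "moderate"),
    (0.90, "high"),
    (1.00, "very high"),
)


def interpret_correlation(r: float) -> str:
    """Band label for |r|: negligible / low / moderate / high / very high."""
    a = abs(float(r))
    if np.isnan(a) or a > 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    for bound, name in _R_BANDS:
        if a <= bound:
            return name
    return "very high"
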