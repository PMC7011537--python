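"""Test-retest reliability between two survey rounds.

For each scale (raw, and collapsed onto the three-level frame for the
finer scales) the module builds round-1 x round-2 transition tables and
derives absolute agreement (percent agreement / percent changes),
chance-corrected agreement (quadratic-weighted Cohen's kappa with a
participant-level bootstrap CI), and the class imbalance that drives the
gap between the two.  Kappa uses disagreement weights ((i-j)/(K-1))^2 so
that coefficients are comparable across scales with different K, and
chance agreement is computed from the two rounds' own marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import RatingsPanel
from .scales import RatingScale, ThreeLevel, map_to_three

__all__ = [
    "TransitionTable",
    "ReliabilityReport",
    "UndefinedStatisticError",
    "transition_table",
    "percent_agreement",
    "percent_changes",
    "quadratic_weights",
    "weighted_kappa",
    "kappa_ci",
    "class_imbalance",
    "interpret_kappa",
    "reliability_report",
]

logger = logging.getLogger(__name__)

THREE_LEVEL_CATEGORIES = tuple(lvl.name for lvl in sorted(ThreeLevel))


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on the given slice (degenerate marginals)."""


@dataclass(frozen=True)
class TransitionTable:
    """K x K cross-tabulation of paired round-1 (rows) x round-2 (columns) ratings.

    Categories are in scale order, least to most important.  ``excluded``
    counts unpaired ratings dropped while pairing the two rounds.
    """

    categories: tuple[str, ...]
    counts: np.ndarray
    excluded: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("transition table must be square")
        if counts.shape[0] != len(self.categories):
            raise ValueError("counts shape does not match category list")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
            counts = np.round(counts).astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def K(self) -> int:
        return len(self.categories)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories), columns=list(self.categories))


def _paired_codes(
    panel: RatingsPanel, scale_id: str, goal: str | None, transformed: bool
) -> tuple[pd.DataFrame, tuple[str, ...], int]:
    """Pair round-1/round-2 ratings as integer category codes.

    Returns (frame with columns participant_id, goal_id, c1, c2), the
    category labels defining the code order, and the number of unpaired
    ratings excluded.
    """
    scale = panel.scales[scale_id]
    df = panel.frame
    sub = df[df["scale_id"] == scale_id]
    if goal is not None:
        sub = sub[sub["goal_id"] == goal]
    if transformed:
        categories = THREE_LEVEL_CATEGORIES
        code = {c: int(map_to_three(scale, c)) for c in scale.categories}
    else:
        categories = scale.categories
        code = {c: i for i, c in enumerate(scale.categories)}
    coded = sub.assign(code=sub["rating"].map(code))
    wide = coded.pivot_table(
        index=["participant_id", "goal_id"], columns="round", values="code", aggfunc="first"
    )
    for r in (1, 2):
        if r not in wide.columns:
            wide[r] = np.nan
    paired = wide.dropna(subset=[1, 2])
    excluded = int(wide[[1, 2]].isna().sum().sum())
    if paired.empty:
        raise UndefinedStatisticError(
            f"no paired round-1/round-2 ratings for scale={scale_id!r} goal={goal!r}"
        )
    if excluded:
        logger.info(
            "transition_table: excluded %d unpaired ratings (scale=%s, goal=%s)",
            excluded, scale_id, goal,
        )
    out = paired.reset_index().rename(columns={1: "c1", 2: "c2"})
    out["c1"] = out["c1"].astype(int)
    out["c2"] = out["c2"].astype(int)
    return out, categories, excluded


def transition_table(
    panel: RatingsPanel,
    scale_id: str,
    goal: str | None = None,
    transformed: bool = False,
) -> TransitionTable:
    """Cross-tabulate paired ratings of the two rounds.

    ``goal=None`` pools every participant x goal pair for the scale
    (the "overall" slice).  With ``transformed=True`` ratings are first
    collapsed onto the three-level frame (K=3); otherwise the scale's
    native K is used.  Unpaired ratings are excluded with a logged count.
    """
    paired, categories, excluded = _paired_codes(panel, scale_id, goal, transformed)
    K = len(categories)
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (paired["c1"].to_numpy(), paired["c2"].to_numpy()), 1)
    return TransitionTable(categories=categories, counts=counts, excluded=excluded)


def percent_agreement(t: TransitionTable) -> float:
    """Share of paired ratings on the diagonal, as a percentage."""
    if t.n < 1:
        raise UndefinedStatisticError("agreement undefined on an empty table")
    return 100.0 * float(np.trace(t.counts)) / t.n


def percent_changes(t: TransitionTable) -> float:
    """Share of paired ratings that changed between rounds; 100 - agreement."""
    return 100.0 - percent_agreement(t)


def quadratic_weights(K: int) -> np.ndarray:
    """Quadratic disagreement weights ((i-j)/(K-1))^2 for K ordered categories."""
    if K < 2:
        raise ValueError(f"need at least 2 categories, got K={K}")
    i = np.arange(K, dtype=float)
    return ((i[:, None] - i[None, :]) / (K - 1)) ** 2


def _kappa_from_counts(counts: np.ndarray) -> float:
    """Quadratic-weighted kappa from a (K, K) count or probability matrix."""
    counts = np.asarray(counts, dtype=float)
    K = counts.shape[-1]
    n = counts.sum()
    o = counts / n
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    v = quadratic_weights(K)
    observed = float((v * o).sum())
    expected = float(row @ v @ col)
    if expected == 0.0:
        if observed == 0.0:
            logger.info("weighted_kappa: degenerate table with zero disagreement; returning 1 by convention")
            return 1.0
        raise UndefinedStatisticError(
            "weighted kappa undefined: zero expected but nonzero observed disagreement"
        )
    return 1.0 - observed / expected


def weighted_kappa(t: TransitionTable) -> float:
    """Quadratic-weighted Cohen's kappa of a transition table.

    Chance agreement uses the product of the table's own row (round 1)
    and column (round 2) marginals.  A table with zero observed *and*
    zero chance-expected weighted disagreement returns 1 by convention;
    zero chance-expected disagreement alone raises
    :class:`UndefinedStatisticError`.
    """
    if t.n < 2:
        raise UndefinedStatisticError("weighted kappa needs at least 2 paired ratings")
    return _kappa_from_counts(t.counts)


def _kappa_vectorized(counts: np.ndarray) -> np.ndarray:
    """Weighted kappa over a (B, K, K) stack; NaN where undefined."""
    n = counts.sum(axis=(-1, -2), keepdims=True)
    o = counts / n
    row = o.sum(axis=-1)
    col = o.sum(axis=-2)
    K = counts.shape[-1]
    v = quadratic_weights(K)
    observed = (v * o).sum(axis=(-1, -2))
    expected = np.einsum("...i,ij,...j->...", row, v, col)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = 1.0 - observed / expected
    k = np.where((expected == 0) & (observed == 0), 1.0, k)
    return np.where(expected == 0, np.where(observed == 0, 1.0, np.nan), k)


def kappa_ci(
    panel: RatingsPanel,
    scale_id: str,
    goal: str | None = None,
    transformed: bool = False,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Participant-level percentile-bootstrap CI for the weighted kappa.

    Participants (not individual ratings) are resampled, so that the
    within-participant clustering of the pooled "overall" slice is
    respected.  Degenerate resamples (undefined kappa) are skipped with a
    logged count.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError(f"need at least 100 bootstrap replicates, got B={B}")
    paired, categories, _ = _paired_codes(panel, scale_id, goal, transformed)
    K = len(categories)
    # per-participant K*K pair-count matrices
    pid_codes, pids = pd.factorize(paired["participant_id"], sort=True)
    P = len(pids)
    cell = paired["c1"].to_numpy() * K + paired["c2"].to_numpy()
    M = np.zeros((P, K * K), dtype=np.int64)
    np.add.at(M, (pid_codes, cell), 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, P, size=(B, P))
    boot = M[idx].sum(axis=1).reshape(B, K, K).astype(float)
    ks = _kappa_vectorized(boot)
    bad = int(np.isnan(ks).sum())
    if bad:
        logger.info("kappa_ci: skipped %d degenerate bootstrap resamples", bad)
    ks = ks[~np.isnan(ks)]
    if ks.size == 0:
        raise UndefinedStatisticError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(ks, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def class_imbalance(
    panel: RatingsPanel,
    scale_id: str,
    round: int,
    transformed: bool = False,
) -> float:
    """Percentage of ratings in the single most frequent category.

    High imbalance (a strongly preferred category) inflates chance
    agreement and depresses kappa relative to percent agreement.
    """
    scale = panel.scales[scale_id]
    df = panel.frame
    sub = df[(df["scale_id"] == scale_id) & (df["round"] == round)]
    if sub.empty:
        raise UndefinedStatisticError(f"no ratings for scale={scale_id!r} round={round}")
    ratings = sub["rating"]
    if transformed:
        ratings = ratings.map(lambda r: map_to_three(scale, r).name)
    freq = ratings.value_counts()
    return 100.0 * float(freq.iloc[0]) / float(len(ratings))


#: Agreement bands for kappa (rule-of-thumb interpretation).
_KAPPA_BANDS = (
    (0.00, "slight"),
    (0.20, "fair"),
    (0.40, "moderate"),
    (0.60, "substantial"),
    (0.80, "almost perfect"),
)


def interpret_kappa(k: float) -> str:
    """Rule-of-thumb label: poor / slight / fair / moderate / substantial / almost perfect."""
    if np.isnan(k):
        raise ValueError("cannot interpret NaN kappa")
    if k < 0.0:
        return "poor"
    label = "slight"
    for bound, name in _KAPPA_BANDS:
        if k > bound:
            label = name
    return label


@dataclass(frozen=True)
class ReliabilityReport:
    """Table-style reliability summary over scale variants.

    ``overall`` has one column per scale variant (raw scales plus the
    collapsed ``*`` variants of scales finer than three levels) and rows
    changes_pct / class_imbalance_round1_pct / agreement_pct /
    weighted_kappa / kappa_ci_low / kappa_ci_high.  ``per_goal`` maps
    each metric to a goals x variants frame; ``summary`` carries the
    unweighted per-goal mean / min / max of each metric.
    """

    overall: pd.DataFrame
    per_goal: Mapping[str, pd.DataFrame]
    summary: pd.DataFrame

    @property
    def variants(self) -> tuple[str, ...]:
        return tuple(self.overall.columns)


def _variant_slices(panel: RatingsPanel) -> list[tuple[str, str, bool]]:
    """(variant label, scale_id, transformed) in report column order."""
    out = [(sid, sid, False) for sid in panel.scales]
    out += [(f"{sid}*", sid, True) for sid in panel.scales if panel.scales[sid].n_categories > 3]
    return out


def reliability_report(
    panel: RatingsPanel,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ReliabilityReport:
    """Assemble the full reliability comparison across scale variants.

    Per-goal metrics omit the bootstrap CI (only the pooled slice gets
    one); the summary rows are the unweighted mean and range over goals.
    """
    rng = np.random.default_rng(seed)
    variants = _variant_slices(panel)
    metrics = ["changes_pct", "class_imbalance_round1_pct", "agreement_pct", "weighted_kappa"]
    overall = pd.DataFrame(index=metrics + ["kappa_ci_low", "kappa_ci_high"], dtype=float)
    per_goal: dict[str, pd.DataFrame] = {
        m: pd.DataFrame(index=list(panel.goals), dtype=float) for m in metrics
    }
    for label, sid, transformed in variants:
        t = transition_table(panel, sid, goal=None, transformed=transformed)
        lo, hi = kappa_ci(panel, sid, goal=None, transformed=transformed, B=B, alpha=alpha, seed=rng)
        overall[label] = [
            percent_changes(t),
            class_imbalance(panel, sid, round=1, transformed=transformed),
            percent_agreement(t),
            weighted_kappa(t),
            lo,
            hi,
        ]
        for goal in panel.goals:
            tg = transition_table(panel, sid, goal=goal, transformed=transformed)
            per_goal["changes_pct"].at[goal, label] = percent_changes(tg)
            per_goal["agreement_pct"].at[goal, label] = percent_agreement(tg)
            try:
                per_goal["weighted_kappa"].at[goal, label] = weighted_kappa(tg)
            except UndefinedStatisticError:
                per_goal["weighted_kappa"].at[goal, label] = np.nan
        imb = _per_goal_imbalance(panel, sid, transformed)
        per_goal["class_imbalance_round1_pct"][label] = imb
    rows = {}
    for m in metrics:
        pg = per_goal[m]
        rows[f"{m}_mean"] = pg.mean(axis=0)
        rows[f"{m}_min"] = pg.min(axis=0)
        rows[f"{m}_max"] = pg.max(axis=0)
    summary = pd.DataFrame(rows).T
    return ReliabilityReport(overall=overall, per_goal=per_goal, summary=summary)


def _per_goal_imbalance(panel: RatingsPanel, scale_id: str, transformed: bool) -> pd.Series:
    scale = panel.scales[scale_id]
    df = panel.frame
    sub = df[(df["scale_id"] == scale_id) & (df["round"] == 1)]
    ratings = sub["rating"]
    if transformed:
        ratings = ratings.map(lambda r: map_to_three(scale, r).name)
    grp = sub.assign(rating=ratings).groupby("goal_id")["rating"]
    out = 100.0 * grp.agg(lambda s: s.value_counts().iloc[0] / len(s))
    return out.reindex(list(panel.goals))
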