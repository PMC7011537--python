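"""Sample size for kappa confidence-interval precision (two ratings per subject).

The planning question: how many subjects must be rated twice so that the
expected (1-alpha) confidence interval around an anticipated kappa0 is
contained in prescribed bounds [kappaL, kappaU]?

The joint behaviour of the two ratings follows the common-correlation
agreement model: with category prevalences pi and agreement kappa, the
probability of category pair (i, j) is

    p_ij = pi_i * pi_j + kappa * pi_i * (delta_ij - pi_j)

The expected CI is built from a goodness-of-fit argument: a candidate
kappa' is at the limit when the Pearson chi-square divergence between the
cell probabilities at kappa0 and at kappa', scaled by n, reaches the
chi-square critical value on 1 degree of freedom.  The minimum n is the
smallest sample size whose expected interval respects both bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

__all__ = [
    "SampleSizeSpec",
    "pair_probabilities",
    "expected_ci_limits",
    "min_sample_size",
]

_BISECT_TOL = 1e-9
_N_CAP = 10**6


@dataclass(frozen=True)
class SampleSizeSpec:
    """Planning parameters for the kappa-CI sample size.

    kappa0 is the anticipated coefficient, (kappaL, kappaU) the bounds the
    expected CI must respect, ``prevalences`` the category probabilities,
    ``raters`` the number of ratings per subject (only 2 supported), and
    ``alpha`` the significance level of the interval.
    """

    kappa0: float
    kappaL: float
    kappaU: float
    prevalences: tuple[float, ...]
    raters: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        prev = tuple(float(p) for p in self.prevalences)
        object.__setattr__(self, "prevalences", prev)
        if len(prev) < 2 or any(p <= 0 for p in prev):
            raise ValueError(f"prevalences must be positive, got {prev}")
        if abs(sum(prev) - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got sum={sum(prev)}")
        if not (0.0 <= self.kappaL < self.kappa0 < self.kappaU <= 1.0):
            raise ValueError(
                f"need 0 <= kappaL < kappa0 < kappaU <= 1, got "
                f"({self.kappaL}, {self.kappa0}, {self.kappaU})"
            )
        if self.raters < 2:
            raise ValueError(f"raters must be >= 2, got {self.raters}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def _kappa_floor(prevalences: np.ndarray) -> float:
    """Smallest admissible kappa (all joint cells non-negative)."""
    return float(-np.min(prevalences / (1.0 - prevalences)))


def pair_probabilities(kappa: float, prevalences: Sequence[float]) -> np.ndarray:
    """Joint K x K category probabilities of two ratings under the model.

    Rows marginalize to the prevalences exactly; kappa=0 gives
    independence, kappa=1 a diagonal matrix.
    """
    pi = np.asarray(prevalences, dtype=float)
    p = np.outer(pi, pi) * (1.0 - kappa) + np.diag(pi) * kappa
    if np.any(p < 0):
        raise ValueError(
            f"inadmissible combination: kappa={kappa} with prevalences {tuple(pi)} "
            f"yields a negative cell (kappa floor is {_kappa_floor(pi):.6f})"
        )
    return p


def _divergence(p0: np.ndarray, kappa: float, pi: np.ndarray) -> float:
    """Pearson chi-square divergence between p(kappa0) and p(kappa)."""
    p1 = pair_probabilities(kappa, pi)
    mask = p1 > 0
    if np.any(~mask & (p0 > 0)):
        return np.inf
    return float(np.sum((p0[mask] - p1[mask]) ** 2 / p1[mask]))


def expected_ci_limits(
    n: int,
    kappa0: float,
    prevalences: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Expected (1-alpha) CI limits for kappa at sample size n.

    The limits straddle kappa0 and the interval narrows as n grows.  A
    limit that cannot be bracketed inside the admissible kappa range is
    clipped to that range boundary (the interval end is then vacuous).
    """
    if n < 10:
        raise ValueError(f"need n >= 10, got n={n}")
    pi = np.asarray(prevalences, dtype=float)
    p0 = pair_probabilities(kappa0, pi)
    crit = float(chi2.ppf(1.0 - alpha, df=1))

    def g(kappa: float) -> float:
        return n * _divergence(p0, kappa, pi) - crit

    floor = _kappa_floor(pi) + 1e-9
    eps = 1e-12
    if g(floor) > 0:
        lower = brentq(g, floor, kappa0 - eps, xtol=_BISECT_TOL)
    else:
        lower = floor
    ceil = 1.0 - 1e-9
    if g(ceil) > 0:
        upper = brentq(g, kappa0 + eps, ceil, xtol=_BISECT_TOL)
    else:
        upper = 1.0
    return float(lower), float(upper)


def _meets(spec: SampleSizeSpec, n: int) -> bool:
    lo, hi = expected_ci_limits(n, spec.kappa0, spec.prevalences, spec.alpha)
    return lo >= spec.kappaL and hi <= spec.kappaU


def min_sample_size(spec: SampleSizeSpec) -> int:
    """Smallest n whose expected CI lies inside [kappaL, kappaU].

    Deterministic: geometric bracketing followed by binary search.  Only
    the two-ratings design is implemented; wider designs raise
    NotImplementedError.
    """
    if spec.raters != 2:
        raise NotImplementedError(f"only raters=2 is implemented, got raters={spec.raters}")
    lo_n, hi_n = 10, 10
    while not _meets(spec, hi_n):
        if hi_n >= _N_CAP:
            raise ValueError(
                f"bounds ({spec.kappaL}, {spec.kappaU}) unreachable for any n <= {_N_CAP}"
            )
        lo_n = hi_n
        hi_n = min(hi_n * 2, _N_CAP)
    if _meets(spec, lo_n):  # already satisfied at the floor
        return lo_n
    while hi_n - lo_n > 1:
        mid = (lo_n + hi_n) // 2
        if _meets(spec, mid):
            hi_n = mid
        else:
            lo_n = mid
    return hi_n
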