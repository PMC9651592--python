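"""Mallows bounds on target coverage and minimal cohort-size search.

P_S = P(n_1 >= k_1, ..., n_r >= k_r) is the probability that one
Multinomial(S, Pvec) allocation meets every per-category target.  Mallows'
inequality brackets it with marginal Binomial tails only:

    1 - sum_j P(n_j < k_j)  <=  P_S  <=  prod_j P(n_j >= k_j)
                                     <=  exp(-sum_j P(n_j < k_j))

The lower (Bonferroni-type) bound is monotone non-decreasing in S, which
justifies bisection for the smallest cohort size whose lower bound reaches a
required success probability.  As S grows the bounds pinch together, so near
the interesting sizes they approximate P_S to a few parts in 10^4 — this is
what makes rare-category sizing tractable without rare-event simulation.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import gammaln, logsumexp

from .demand import DemandProfile, InvalidInputError, TargetVector
from .multinomial import marginal_tail

__all__ = [
    "BoundsResult",
    "SizingResult",
    "mallows_bounds",
    "exact_coverage",
    "minimal_sample_size",
]

DEFAULT_COMPOSITION_CAP = 2_000_000


@dataclass(frozen=True)
class BoundsResult:
    """Mallows bounds on P_S at one cohort size ``S``."""

    S: int
    lower: float
    upper_product: float
    upper_exp: float
    feasible: bool = True
    exact: float | None = None


@dataclass(frozen=True)
class SizingResult:
    """Minimal cohort size ``S_C`` whose lower bound reaches ``C``/100."""

    C: float
    S_C: int
    bounds: BoundsResult
    panel_fraction: float | None = None


def _tail_vectors(
    S: int, profile: DemandProfile, targets: TargetVector
) -> tuple[np.ndarray, np.ndarray]:
    below = np.empty(profile.r)
    above = np.empty(profile.r)
    for j, (p, k) in enumerate(zip(profile.probabilities, targets.targets)):
        below[j], above[j] = marginal_tail(S, float(p), int(k))
    return below, above


def mallows_bounds(
    S: int, profile: DemandProfile, targets: TargetVector
) -> BoundsResult:
    """Evaluate the Mallows lower and upper bounds at cohort size ``S``.

    When ``S < K`` the targets cannot all be met (pigeonhole), the exact
    coverage is zero, and the result is flagged infeasible with lower bound 0.
    """
    if profile.r != targets.r:
        raise InvalidInputError("profile and targets have different lengths")
    below, above = _tail_vectors(S, profile, targets)
    total_below = float(below.sum())
    lower = max(0.0, 1.0 - total_below)
    upper_product = float(np.prod(above))
    upper_exp = float(math.exp(-total_below))
    feasible = S >= targets.K
    if not feasible:
        lower = 0.0
    return BoundsResult(
        S=S,
        lower=lower,
        upper_product=upper_product,
        upper_exp=upper_exp,
        feasible=feasible,
    )


def exact_coverage(
    S: int,
    profile: DemandProfile,
    targets: TargetVector,
    cap: int = DEFAULT_COMPOSITION_CAP,
) -> float:
    """Exact P_S by exhaustive enumeration — a brute-force oracle.

    Sums the Multinomial pmf over every allocation meeting all targets,
    enumerated as compositions of the surplus ``S - K`` shifted by the
    targets.  Refuses (so the caller falls back on the bounds) when the
    number of terms exceeds ``cap``; plain enumeration is only feasible for
    small ``r`` and ``S``.
    """
    if profile.r != targets.r:
        raise InvalidInputError("profile and targets have different lengths")
    K = targets.K
    if S < K:
        return 0.0
    surplus = S - K
    r = profile.r
    n_terms = math.comb(surplus + r - 1, r - 1)
    if n_terms > cap:
        raise InvalidInputError(
            f"{n_terms} compositions exceed the enumeration cap of {cap}"
        )
    logp = np.log(profile.probabilities)
    base = targets.targets.astype(np.int64)
    log_terms = np.empty(n_terms)
    lg_S1 = gammaln(S + 1)
    for i, dividers in enumerate(
        itertools.combinations(range(surplus + r - 1), r - 1)
    ):
        comp = np.diff(np.concatenate(([-1], dividers, [surplus + r - 1]))) - 1
        n = base + comp
        log_terms[i] = lg_S1 - gammaln(n + 1).sum() + (n * logp).sum()
    return float(np.exp(logsumexp(log_terms)))


def minimal_sample_size(
    profile: DemandProfile,
    targets: TargetVector,
    C: float,
    search: Literal["bisection", "linear"] = "bisection",
    step: int = 100,
    panel_size: int | None = None,
) -> SizingResult:
    """Smallest cohort size whose Mallows lower bound reaches ``C`` percent.

    The search runs on the lattice ``S = K + i*step`` (``step=100`` matches
    3-significant-figure reporting; ``step=1`` gives the exact minimum).  The
    lower bound is monotone non-decreasing in S, so bisection between a
    failing and a doubled passing lattice point finds the same answer as a
    linear scan.
    """
    if not 0.0 < C < 100.0:
        raise InvalidInputError("C must lie strictly between 0 and 100")
    if step < 1:
        raise InvalidInputError("step must be a positive integer")
    if search not in ("bisection", "linear"):
        raise InvalidInputError(f"unknown search mode {search!r}")
    threshold = C / 100.0
    K = targets.K

    def lower_at(i: int) -> float:
        return mallows_bounds(K + i * step, profile, targets).lower

    if lower_at(0) >= threshold:
        bounds = mallows_bounds(K, profile, targets)
        return SizingResult(
            C=C,
            S_C=K,
            bounds=bounds,
            panel_fraction=(K / panel_size if panel_size else None),
        )

    if search == "linear":
        i = 1
        while lower_at(i) < threshold:
            i += 1
        hi = i
    else:
        hi = 1
        while lower_at(hi) < threshold:
            hi *= 2
        lo = hi // 2  # fails (or is 0, which failed above)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if lower_at(mid) >= threshold:
                hi = mid
            else:
                lo = mid

    S_C = K + hi * step
    bounds = mallows_bounds(S_C, profile, targets)
    return SizingResult(
        C=C,
        S_C=S_C,
        bounds=bounds,
        panel_fraction=(S_C / panel_size if panel_size else None),
    )
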