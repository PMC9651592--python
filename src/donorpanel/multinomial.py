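"""Multinomial allocation model for typed-donor panels.

``S`` donors walk in at random and each is assigned to exactly one of ``r``
antigen-combination categories with the demand probabilities ``Pvec``.  The
per-category counts ``Nvec`` are then one Multinomial(S, Pvec) draw, and each
marginal count is Binomial(S, p_j).  Everything downstream (Mallows bounds,
Monte Carlo validation) is built on these four primitives.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

from .demand import DemandProfile, InvalidInputError

__all__ = [
    "AllocationResult",
    "MarginalMoments",
    "multinomial_logpmf",
    "multinomial_pmf",
    "marginal_moments",
    "marginal_tail",
    "sample_allocation",
]


@dataclass(frozen=True)
class AllocationResult:
    """One assignment of ``S`` donors to categories (``Nvec``)."""

    counts: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.size == 0 or (counts < 0).any():
            raise InvalidInputError("counts must be non-empty and non-negative")

    @property
    def S(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MarginalMoments:
    """Per-category expectation ``p_i S`` and variance ``p_i (1-p_i) S``."""

    expectation: np.ndarray
    variance: np.ndarray


def _counts_array(counts: AllocationResult | np.ndarray) -> np.ndarray:
    if isinstance(counts, AllocationResult):
        return counts.counts
    return np.asarray(counts, dtype=np.int64)


def multinomial_logpmf(
    counts: AllocationResult | np.ndarray, profile: DemandProfile
) -> float:
    """Log of the Multinomial pmf, stable for cohort sizes in the 10^5 range.

    log P = log S! - sum log n_j! + sum n_j log p_j, via log-gamma.
    """
    n = _counts_array(counts)
    if n.ndim != 1 or n.size != profile.r:
        raise InvalidInputError(
            f"counts length {n.size} does not match profile with r={profile.r}"
        )
    S = n.sum()
    logp = np.log(profile.probabilities)
    return float(gammaln(S + 1) - gammaln(n + 1).sum() + (n * logp).sum())


def multinomial_pmf(
    counts: AllocationResult | np.ndarray, profile: DemandProfile
) -> float:
    """Probability of one specific allocation ``Nvec`` under the model."""
    return float(np.exp(multinomial_logpmf(counts, profile)))


def marginal_moments(S: int, profile: DemandProfile) -> MarginalMoments:
    """Mean and variance of each category count (marginals are Binomial)."""
    if S < 1:
        raise InvalidInputError("S must be a positive integer")
    p = profile.probabilities
    return MarginalMoments(expectation=p * S, variance=p * (1.0 - p) * S)


def marginal_tail(S: int, p: float, k: int) -> tuple[float, float]:
    """Exact Binomial tail split at a target ``k``.

    Returns ``(below, at_or_above)`` with ``below = P(n_j < k)`` (the Binomial
    CDF at ``k-1``, exact via the regularized incomplete beta function — no
    normal approximation) and ``at_or_above = 1 - below`` exactly.  An
    unreachable target ``k > S`` gives ``(1, 0)``.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError("p must lie in [0, 1]")
    if k < 0:
        raise InvalidInputError("k must be non-negative")
    if k == 0:
        return 0.0, 1.0
    if k > S:
        return 1.0, 0.0
    below = float(binom.cdf(k - 1, S, p))
    return below, 1.0 - below


def sample_allocation(
    S: int,
    profile: DemandProfile,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AllocationResult:
    """Draw one Multinomial(S, Pvec) allocation.

    Uses numpy's PCG64 generator; the same ``seed`` with the same inputs
    always reproduces the same counts.  Passing an explicit ``rng`` lets a
    caller thread its own generator (the seed is then not recorded).
    """
    if S < 1:
        raise InvalidInputError("S must be a positive integer")
    if rng is None:
        rng = np.random.default_rng(seed)
    else:
        seed = None
    counts = rng.multinomial(S, profile.probabilities)
    return AllocationResult(counts=counts, seed=seed)
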