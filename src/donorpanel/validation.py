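"""Monte Carlo Multinomial validation of cohort-size estimates.

For a candidate cohort size ``S``, repeated Multinomial allocations are drawn
and each sample is scored by its *success percentage*: 100 x (1 - failures/r),
where a failure is a category whose sampled donor count falls below its
target.  The headline statistic is the MINIMUM success percentage over all
samples — a size is accepted when even the worst of 10,000 samples meets the
required percentage — with the mean and the zero-failure fraction reported
alongside as diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .demand import DemandProfile, InvalidInputError, TargetVector
from .multinomial import AllocationResult

__all__ = [
    "MCSummary",
    "SweepRow",
    "success_percentage",
    "run_validation",
    "sweep_multiples",
    "plot_allocations",
]


@dataclass(frozen=True)
class MCSummary:
    """Summary of one Monte Carlo validation run at cohort size ``S``."""

    S: int
    n_samples: int
    min_success_pct: float
    mean_success_pct: float
    all_targets_met_fraction: float
    failures_per_sample: dict[str, float]
    seed: int | None


@dataclass(frozen=True)
class SweepRow:
    """One row of an S-versus-K sweep: ``S`` as a multiple of ``K``."""

    multiplier: float
    S: int
    summary: MCSummary

    @property
    def min_success_pct(self) -> float:
        return self.summary.min_success_pct


def success_percentage(
    allocation: AllocationResult | np.ndarray, targets: TargetVector
) -> float:
    """100 x (1 - failures/r) for one allocation against its targets."""
    n = allocation.counts if isinstance(allocation, AllocationResult) else np.asarray(allocation)
    if n.size != targets.r:
        raise InvalidInputError("allocation and targets have different lengths")
    failures = int(np.count_nonzero(n - targets.targets < 0))
    return 100.0 * (1.0 - failures / targets.r)


def _failure_counts(
    S: int,
    profile: DemandProfile,
    targets: TargetVector,
    n_samples: int,
    seed: int | None,
) -> np.ndarray:
    # sample i draws from a generator spawned deterministically from (seed, i),
    # so runs parallelize and reproduce independently of batch size
    children = np.random.SeedSequence(seed).spawn(n_samples)
    k = targets.targets
    failures = np.empty(n_samples, dtype=np.int64)
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        counts = rng.multinomial(S, profile.probabilities)
        failures[i] = np.count_nonzero(counts < k)
    return failures


def run_validation(
    S: int,
    profile: DemandProfile,
    targets: TargetVector,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> MCSummary:
    """Draw ``n_samples`` Multinomial allocations and summarise success.

    Identical ``seed`` and inputs give an identical summary.
    """
    if profile.r != targets.r:
        raise InvalidInputError("profile and targets have different lengths")
    if n_samples < 1:
        raise InvalidInputError("n_samples must be a positive integer")
    failures = _failure_counts(S, profile, targets, n_samples, seed)
    success = 100.0 * (1.0 - failures / targets.r)
    return MCSummary(
        S=S,
        n_samples=n_samples,
        min_success_pct=float(success.min()),
        mean_success_pct=float(success.mean()),
        all_targets_met_fraction=float(np.mean(failures == 0)),
        failures_per_sample={
            "mean": float(failures.mean()),
            "max": int(failures.max()),
            "p50": float(np.percentile(failures, 50)),
            "p99": float(np.percentile(failures, 99)),
        },
        seed=seed,
    )


def sweep_multiples(
    profile: DemandProfile,
    targets: TargetVector,
    multipliers: Sequence[float],
    n_samples: int = 10_000,
    seed: int | None = None,
) -> list[SweepRow]:
    """Validate at ``S = round(mu * K)`` for each multiplier ``mu``.

    Integral multipliers reproduce exact ``mu*K`` products.  Each row gets
    its own sub-seed derived from ``seed`` so rows are independent.
    """
    if any(m <= 0 for m in multipliers):
        raise InvalidInputError("multipliers must be positive")
    K = targets.K
    row_seeds = np.random.SeedSequence(seed).generate_state(len(multipliers))
    rows = []
    for mu, row_seed in zip(multipliers, row_seeds):
        S = int(round(mu * K))
        summary = run_validation(
            S, profile, targets, n_samples=n_samples, seed=int(row_seed)
        )
        rows.append(SweepRow(multiplier=float(mu), S=S, summary=summary))
    return rows


def plot_allocations(
    profile: DemandProfile,
    targets: TargetVector,
    allocations: Sequence[AllocationResult],
    path: str | Path,
    n_categories: int = 30,
    which: str = "top",
) -> None:
    """Grouped bar chart: targets vs sampled allocations for the highest-
    or lowest-probability categories, written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(profile.probabilities)[::-1]
    idx = order[:n_categories] if which == "top" else order[-n_categories:]
    labels = [profile.labels[i] for i in idx]
    width = 1.0 / (len(allocations) + 2)
    x = np.arange(len(idx))
    fig, ax = plt.subplots(figsize=(max(8, len(idx) * 0.4), 4.5))
    ax.bar(x, targets.targets[idx], width, label="target", color="tab:blue")
    for a_i, alloc in enumerate(allocations, start=1):
        ax.bar(x + a_i * width, alloc.counts[idx], width, label=f"sample {a_i}")
    ax.set_xticks(x + width * len(allocations) / 2)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("donors")
    ax.set_xlabel("antigen combination")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
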