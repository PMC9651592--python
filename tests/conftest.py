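import numpy as np
import pytest

from donorpanel import (
    AntigenCombination,
    DemandProfile,
    RequestTable,
    TargetVector,
    generate_profile,
    genotype_spec,
)


def profile_from_probs(probs) -> DemandProfile:
    """Small demand profile with synthetic placeholder labels."""
    probs = np.asarray(probs, dtype=float)
    combos = tuple(
        AntigenCombination.from_label(f"A{i + 1}-") for i in range(probs.size)
    )
    return DemandProfile(combos, probs)


def table_from_counts(counts, period_days=365) -> RequestTable:
    labels = [f"A{i + 1}-" for i in range(len(counts))]
    return RequestTable.from_labels(labels, counts, period_days)


def random_small_instance(rng, r_max=4, S_max=12):
    """Random (S, profile, targets) small enough for exhaustive enumeration."""
    r = int(rng.integers(2, r_max + 1))
    p = rng.dirichlet(np.ones(r))
    p = np.clip(p, 1e-6, None)
    p = p / p.sum()
    k = rng.integers(0, 4, size=r)
    S = int(rng.integers(1, S_max + 1))
    return S, profile_from_probs(p), TargetVector(k)


@pytest.fixture(scope="session")
def genotype_profile() -> DemandProfile:
    return generate_profile(genotype_spec(seed=0))


@pytest.fixture(scope="session")
def coin_profile() -> DemandProfile:
    return profile_from_probs([0.5, 0.5])
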