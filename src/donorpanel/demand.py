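"""Demand estimation from historical antigen-negative request tables.

A transfusion request names an *antigen combination*: the set of red-cell
antigens the unit must test negative for, written as a dash-terminated label
such as ``"c-E-K-"``.  Historical request counts per combination are turned
into a categorical demand distribution (one probability per combination) and
into per-category donor targets for a chosen planning window.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AntigenCombination",
    "RequestTable",
    "DemandProfile",
    "TargetVector",
    "estimate_probabilities",
    "build_targets",
    "read_request_table",
    "read_profile",
    "write_profile",
]

# one antigen token, e.g. "c", "E", "Fya", "Sc1", each terminated by "-"
_TOKEN_RE = re.compile(r"([A-Za-z][A-Za-z0-9^]*)-")


class InvalidInputError(ValueError):
    """Raised when an input table, label or parameter is malformed."""


@dataclass(frozen=True)
class AntigenCombination:
    """A set of antigens a red-cell unit must be negative for."""

    label: str
    antigens: frozenset[str]

    @classmethod
    def from_label(cls, label: str) -> "AntigenCombination":
        if not label:
            raise InvalidInputError("empty antigen-combination label")
        tokens = _TOKEN_RE.findall(label)
        if "".join(f"{t}-" for t in tokens) != label:
            raise InvalidInputError(
                f"label {label!r} is not a dash-terminated antigen combination"
            )
        return cls(label=label, antigens=frozenset(tokens))


def _check_unique_labels(labels: Sequence[str]) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise InvalidInputError(f"duplicate antigen-combination label {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class RequestTable:
    """Raw request counts per antigen combination over a collection period."""

    combinations: tuple[AntigenCombination, ...]
    counts: np.ndarray  # non-negative integers, same length
    period_days: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if len(self.combinations) != counts.size:
            raise InvalidInputError("combinations and counts have different lengths")
        if counts.size == 0 or (counts < 0).any():
            raise InvalidInputError("counts must be a non-empty non-negative vector")
        if int(counts.sum()) == 0:
            raise InvalidInputError("request table needs at least one positive count")
        if self.period_days <= 0:
            raise InvalidInputError("period_days must be a positive integer")
        _check_unique_labels([c.label for c in self.combinations])

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.combinations]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(
        cls,
        labels: Iterable[str],
        counts: Iterable[int],
        period_days: int,
    ) -> "RequestTable":
        combos = tuple(AntigenCombination.from_label(l) for l in labels)
        return cls(combos, np.asarray(list(counts), dtype=np.int64), period_days)


@dataclass(frozen=True)
class DemandProfile:
    """Categorical demand distribution over antigen combinations (``Pvec``)."""

    combinations: tuple[AntigenCombination, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if len(self.combinations) != p.size or p.size == 0:
            raise InvalidInputError("combinations and probabilities length mismatch")
        if (p <= 0).any() or (p > 1).any():
            raise InvalidInputError("all category probabilities must lie in (0, 1]")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise InvalidInputError(
                f"probabilities must sum to 1 (got {float(p.sum()):.12f})"
            )
        _check_unique_labels([c.label for c in self.combinations])

    @property
    def r(self) -> int:
        """Number of distinct antigen-combination categories."""
        return len(self.combinations)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.combinations]


@dataclass(frozen=True)
class TargetVector:
    """Per-category integer donor targets (``Kvec``) and their sum ``K``."""

    targets: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.targets, dtype=np.int64)
        object.__setattr__(self, "targets", k)
        if k.size == 0 or (k < 0).any():
            raise InvalidInputError("targets must be a non-empty non-negative vector")

    @property
    def K(self) -> int:
        return int(self.targets.sum())

    @property
    def r(self) -> int:
        return self.targets.size


def estimate_probabilities(table: RequestTable) -> DemandProfile:
    """Estimate category probabilities as request frequencies.

    Each category's probability is its request count divided by the total
    number of requests.  Zero-count rows carry no probability mass and are
    dropped, so the resulting profile covers exactly the requested
    combinations; input ordering is preserved otherwise.
    """
    mask = table.counts > 0
    counts = table.counts[mask]
    combos = tuple(c for c, keep in zip(table.combinations, mask) if keep)
    p = counts / counts.sum()
    return DemandProfile(combos, p)


def build_targets(
    table: RequestTable,
    window_days: int | None = None,
    mode: Literal["per-request", "at-least-one"] = "per-request",
) -> TargetVector:
    """Build per-category donor targets for a planning window.

    ``per-request`` scales each count to the window proportionally and takes
    the ceiling, so every requested category keeps a non-zero target even in
    short windows.  ``at-least-one`` sets every requested category's target
    to one donor (the coverage regime used for panel sizing).

    Zero-count rows are dropped, keeping targets aligned with the profile
    returned by :func:`estimate_probabilities` for the same table.
    """
    mask = table.counts > 0
    counts = table.counts[mask]
    if mode == "at-least-one":
        return TargetVector(np.ones(counts.size, dtype=np.int64))
    if mode != "per-request":
        raise InvalidInputError(f"unknown target mode {mode!r}")
    if window_days is None or window_days <= 0:
        raise InvalidInputError("per-request targets need a positive window_days")
    if window_days > table.period_days:
        raise InvalidInputError(
            f"window_days={window_days} exceeds table period of {table.period_days} days"
        )
    # integer ceiling of count * window / period
    k = -(-counts * window_days // table.period_days)
    return TargetVector(k.astype(np.int64))


# ---------------------------------------------------------------------------
# file IO: CSV/TSV with header label,count (requests) or label,probability


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; dtype=str defers numeric parsing so
    # probabilities can be converted with python's correctly-rounded float()
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_request_table(path: str | Path, period_days: int) -> RequestTable:
    """Read a ``label,count`` CSV/TSV into a :class:`RequestTable`."""
    df = _read_delimited(path)
    cols = {c.lower(): c for c in df.columns}
    if "label" not in cols or "count" not in cols:
        raise InvalidInputError(f"{path}: expected columns 'label' and 'count'")
    return RequestTable.from_labels(
        df[cols["label"]].astype(str), df[cols["count"]].astype(int), period_days
    )


def read_profile(path: str | Path) -> DemandProfile:
    """Read a demand profile from ``label,probability`` or ``label,count``.

    Both dialects are accepted so a published per-category probability table
    can be supplied verbatim in place of raw request counts.
    """
    df = _read_delimited(path)
    cols = {c.lower(): c for c in df.columns}
    if "label" not in cols:
        raise InvalidInputError(f"{path}: expected a 'label' column")
    combos = tuple(
        AntigenCombination.from_label(str(l)) for l in df[cols["label"]]
    )
    if "probability" in cols:
        # python float() is correctly rounded, so written repr values
        # round-trip bit-exactly (pandas' own parser may be off by one ulp)
        p = np.array([float(x) for x in df[cols["probability"]].astype(str)])
        return DemandProfile(combos, p / p.sum() if abs(p.sum() - 1) > 1e-9 else p)
    if "count" in cols:
        table = RequestTable.from_labels(
            df[cols["label"]].astype(str), df[cols["count"]].astype(int), period_days=1
        )
        return estimate_probabilities(table)
    raise InvalidInputError(f"{path}: expected a 'probability' or 'count' column")


def write_profile(
    profile: DemandProfile,
    path: str | Path,
    metadata_path: str | Path | None = None,
    total_requests: int | None = None,
) -> None:
    """Write ``label,probability`` CSV; floats use repr so re-reading is exact."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("label,probability\n")
        for lab, p in zip(profile.labels, profile.probabilities):
            fh.write(f"{lab},{float(p)!r}\n")
    if metadata_path is not None:
        meta = {"r": profile.r, "total_requests": total_requests}
        Path(metadata_path).write_text(json.dumps(meta, indent=2) + "\n")
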