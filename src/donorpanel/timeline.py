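"""Screened-panel growth under donor attrition, and maintenance rates.

Each year a fraction ``m`` of already-screened donors stops returning, while
``q`` donors are newly screened; a donor screened during the year has on
average been on the panel for six months, so the new intake loses ``m/2`` in
its first year.  With ``M = q(1 - m/2)`` the screened panel evolves as

    D_{y+1} = (1 - m) D_y + M

whose closed form is

    D_y = (1 - m)^y D_0 + (M/m) (1 - (1 - m)^y),

converging monotonically to the steady state ``M/m``.  Inverting for the
first year that reaches a target size, or for the screening fraction needed
to reach it by a deadline, gives planning timelines; setting D_{y+1} = D_y
at the target gives the annual screening rate that holds the panel steady.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .demand import InvalidInputError

__all__ = [
    "PanelParams",
    "TimelineResult",
    "annual_screened",
    "panel_after_years",
    "years_to_target",
    "required_fraction",
    "maintenance_rate",
]

WEEKS_PER_YEAR = 365 / 7


def annual_screened(weekly_returning: float, fraction: float) -> int:
    """Donors screened per annum: weekly returning donors x screened fraction
    x 365/7, rounded to the nearest integer."""
    if weekly_returning < 0 or fraction < 0:
        raise InvalidInputError("inputs must be non-negative")
    return int(round(weekly_returning * fraction * WEEKS_PER_YEAR))


@dataclass(frozen=True)
class PanelParams:
    """Donor-retention parameters for one screening scenario.

    ``round_q=True`` (default) rounds the annual screening count to a whole
    number of donors before projecting; the unrounded rate is also supported
    since either convention changes year-12 panel sizes by only a couple of
    donors.
    """

    panel_size: int
    weekly_returning: float
    screening_fraction: float
    D0: float
    m: float
    round_q: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.m < 1.0:
            raise InvalidInputError("m must lie in [0, 1)")
        if not 0.0 <= self.screening_fraction <= 1.0:
            raise InvalidInputError("screening_fraction must lie in [0, 1]")
        if self.D0 < 0 or self.weekly_returning < 0:
            raise InvalidInputError("D0 and weekly_returning must be non-negative")

    @property
    def q(self) -> float:
        """Donors screened per annum."""
        exact = self.weekly_returning * self.screening_fraction * WEEKS_PER_YEAR
        return float(round(exact)) if self.round_q else exact

    @property
    def M(self) -> float:
        """Effective annual intake q(1 - m/2), first-year attrition applied."""
        return self.q * (1.0 - self.m / 2.0)

    @property
    def steady_state(self) -> float:
        """Limiting panel size M/m (infinite when there is no attrition)."""
        if self.m == 0.0:
            return math.inf
        return self.M / self.m


@dataclass(frozen=True)
class TimelineResult:
    """Years to reach a target (None = never) and the panel trajectory."""

    years: int | None
    D_y: float
    trajectory: tuple[float, ...]
    steady_state: float


def panel_after_years(params: PanelParams, y: int) -> float:
    """Average screened-panel size after ``y`` whole years (closed form)."""
    if y < 0:
        raise InvalidInputError("y must be a non-negative integer")
    if params.m == 0.0:
        return params.D0 + params.M * y
    decay = (1.0 - params.m) ** y
    return decay * params.D0 + params.steady_state * (1.0 - decay)


def years_to_target(params: PanelParams, target: float) -> TimelineResult:
    """Smallest whole number of years with ``D_y >= target``.

    Returns ``years=None`` ("never") when attrition caps the panel below the
    target: the trajectory approaches ``M/m`` from below and stalls.
    """
    if target <= 0:
        raise InvalidInputError("target must be positive")
    steady = params.steady_state
    if params.D0 >= target:
        return TimelineResult(
            years=0, D_y=params.D0, trajectory=(), steady_state=steady
        )
    reachable = steady > target or (params.m == 0.0 and params.M > 0)
    if not reachable:
        return TimelineResult(
            years=None, D_y=params.D0, trajectory=(), steady_state=steady
        )
    # analytic bound on the horizon, then walk the closed form year by year
    if params.m == 0.0:
        horizon = math.ceil((target - params.D0) / params.M)
    else:
        ratio = (steady - target) / (steady - params.D0)
        horizon = math.ceil(math.log(ratio) / math.log(1.0 - params.m))
    trajectory: list[float] = []
    for y in range(1, horizon + 2):
        D = panel_after_years(params, y)
        trajectory.append(D)
        if D >= target:
            return TimelineResult(
                years=y, D_y=D, trajectory=tuple(trajectory), steady_state=steady
            )
    raise AssertionError("unreachable: horizon bound exceeded")  # pragma: no cover


def required_fraction(
    params: PanelParams,
    target: float,
    deadline_years: int | None = None,
    grid_step: float = 0.01,
) -> tuple[float, TimelineResult] | None:
    """Smallest screening fraction (on a grid) reaching ``target`` in time.

    Scans fractions ``grid_step, 2*grid_step, ... , 1`` and returns the first
    whose timeline attains the target within ``deadline_years`` (or at all,
    when no deadline is given).  ``None`` means no fraction up to 100%
    suffices.  ``params.screening_fraction`` is ignored.
    """
    if deadline_years is not None and deadline_years < 1:
        raise InvalidInputError("deadline_years must be at least 1")
    if not 0.0 < grid_step <= 1.0:
        raise InvalidInputError("grid_step must lie in (0, 1]")
    n_steps = int(round(1.0 / grid_step))
    for i in range(1, n_steps + 1):
        fraction = min(1.0, i * grid_step)
        result = years_to_target(
            replace(params, screening_fraction=fraction), target
        )
        if result.years is None:
            continue
        if deadline_years is None or result.years <= deadline_years:
            return fraction, result
    return None


def maintenance_rate(target: float, m: float) -> float:
    """Annual screenings holding a panel of size ``target`` steady.

    From the fixed point D_{y+1} = D_y = target: q(1 - m/2) = m * target,
    so q = m * target / (1 - m/2).  Zero attrition needs zero replacement.
    """
    if target <= 0:
        raise InvalidInputError("target must be positive")
    if not 0.0 <= m < 1.0:
        raise InvalidInputError("m must lie in [0, 1)")
    if m == 0.0:
        return 0.0
    return m * target / (1.0 - m / 2.0)
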