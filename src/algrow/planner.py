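"""Cultivation planning: choose the initial medium concentration and the
incident light flux that deliver a target biomass at a target time.

The planner exploits a structural feature of the model: the stationary
biomass has the closed form ``N_max = min(C0/alpha + N0, Gamma)`` and is
independent of the light flux, which only sets the pace.  So the medium
concentration is solved analytically for the biomass target, and the
light flux is then chosen by scanning full-model simulations for the
candidate whose harvest window brackets the target time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core_model import (
    CultureCondition,
    CultureGeometry,
    DEFAULT_GEOMETRY,
    ModelParams,
    cells_from_od,
)
from .simulator import GrowthCurve, HorizonError, crossing_times, simulate_full

__all__ = [
    "PlanSpec",
    "PlanResult",
    "InfeasibleTargetError",
    "max_biomass",
    "required_c0",
    "harvest_window",
    "select_ein",
    "plan",
    "DEFAULT_EIN_CANDIDATES",
]

#: Default light-flux candidates, μE s⁻¹ (the four-step neutral-filter panel).
DEFAULT_EIN_CANDIDATES = (0.274, 0.521, 1.09, 2.92)


class InfeasibleTargetError(ValueError):
    """The biomass target cannot be reached for any medium concentration."""


@dataclass(frozen=True)
class PlanSpec:
    """Planning targets.

    ``target_biomass`` is in cells; use :func:`algrow.core_model.cells_from_od`
    for an OD-denominated target.  ``harvest_fractions`` bound the harvest
    window as fractions of the stationary biomass.  ``target_fraction``
    places the target inside that band: cultures are harvested before
    stationary phase, so the medium is dosed for a stationary biomass of
    ``target_biomass / target_fraction`` (set it to ``None`` to treat the
    target as the stationary biomass itself).
    """

    target_biomass: float
    target_time: float
    harvest_fractions: tuple[float, float] = (0.7, 0.9)
    target_fraction: float | None = 0.8
    ein_candidates: Sequence[float] = DEFAULT_EIN_CANDIDATES

    def __post_init__(self) -> None:
        lo, hi = self.harvest_fractions
        if not (0 < lo < hi <= 1):
            raise ValueError("harvest_fractions must satisfy 0 < lower < upper <= 1")
        if self.target_fraction is not None and not (lo <= self.target_fraction <= hi):
            raise ValueError("target_fraction must lie within harvest_fractions")
        if self.target_time <= 0:
            raise ValueError("target_time must be positive")
        if self.target_biomass <= 0:
            raise ValueError("target_biomass must be positive")
        if not self.ein_candidates:
            raise ValueError("ein_candidates must be non-empty")


@dataclass
class PlanResult:
    c0_star: float
    ein_star: float | None
    n_max_pred: float
    t1: float | None
    t2: float | None
    feasible: bool
    predicted_curve: GrowthCurve | None = None
    #: (e_in, T1, T2) for every scanned candidate, for reporting.
    windows: list[tuple[float, float, float]] = field(default_factory=list)


def max_biomass(condition: CultureCondition, params: ModelParams) -> float:
    """Stationary-phase biomass ``min(C0/alpha + N0, Gamma)``, cell.

    Growth stops when either the medium is depleted (first branch) or the
    logistic carrying capacity is hit; independent of the light flux.
    """
    return min(condition.c0 / params.alpha + condition.n0, params.gamma_cap)


def required_c0(target_biomass: float, n0: float, params: ModelParams) -> float:
    """Initial medium concentration whose stationary biomass equals the target.

    Inverts the medium-limited branch: ``C0* = alpha · (N* − N0)``.  Exact
    inverse of :func:`max_biomass` for targets below the carrying capacity.
    """
    if target_biomass > params.gamma_cap * (1 + 1e-12):
        raise InfeasibleTargetError(
            f"target biomass {target_biomass:.4g} exceeds the carrying capacity "
            f"{params.gamma_cap:.4g}; no medium concentration can reach it"
        )
    if target_biomass <= n0:
        raise ValueError("target biomass must exceed the initial biomass n0")
    return params.alpha * (target_biomass - n0)


def harvest_window(
    condition: CultureCondition,
    params: ModelParams,
    fractions: tuple[float, float] = (0.7, 0.9),
) -> tuple[float, float]:
    """First-crossing times (T1, T2) of ``lower·N_max`` and ``upper·N_max``, h.

    Simulates the full model; crossings are located with the integrator's
    event root-finding, so they do not depend on any output grid.
    """
    lo, hi = fractions
    if not (0 < lo <= hi < 1 + 1e-12):
        raise ValueError("fractions must satisfy 0 < lower <= upper < 1")
    if condition.e_in <= 0:
        raise ValueError("harvest window requires e_in > 0")
    n_max = max_biomass(condition, params)
    targets = [lo * n_max, hi * n_max]
    if math.isclose(lo, hi):
        t = crossing_times(condition, params, [targets[0]])[0]
        return (t, t)
    t1, t2 = crossing_times(condition, params, targets)
    return (t1, t2)


def select_ein(
    spec: PlanSpec,
    c0_star: float,
    params: ModelParams,
    geometry: CultureGeometry = DEFAULT_GEOMETRY,
    n0: float | None = None,
) -> PlanResult:
    """Scan the light-flux candidates and pick the one whose harvest window
    contains the target time (ties broken toward the dimmest candidate,
    i.e. the lowest energy cost).

    If no window contains the target time the result is flagged
    infeasible and the candidate with the nearest window is reported.
    """
    if n0 is None:
        n0 = CultureCondition.from_od0(1.0, 1.0, geometry=geometry).n0
    windows: list[tuple[float, float, float]] = []
    for e_in in sorted(spec.ein_candidates):
        cond = CultureCondition(e_in=e_in, c0=c0_star, n0=n0, geometry=geometry)
        try:
            t1, t2 = harvest_window(cond, params, spec.harvest_fractions)
        except HorizonError:
            continue
        windows.append((e_in, t1, t2))
    if not windows:
        raise InfeasibleTargetError("no candidate reached the harvest fractions")

    n_max = max_biomass(
        CultureCondition(e_in=windows[0][0], c0=c0_star, n0=n0, geometry=geometry), params
    )
    t_star = spec.target_time
    containing = [w for w in windows if w[1] <= t_star <= w[2]]
    if containing:
        e_in, t1, t2 = min(containing, key=lambda w: w[0])
        feasible = True
    else:
        e_in, t1, t2 = min(windows, key=lambda w: min(abs(t_star - w[1]), abs(t_star - w[2])))
        feasible = False
    cond = CultureCondition(e_in=e_in, c0=c0_star, n0=n0, geometry=geometry)
    curve = simulate_full(cond, params)
    return PlanResult(
        c0_star=c0_star,
        ein_star=e_in if feasible else None,
        n_max_pred=n_max,
        t1=t1,
        t2=t2,
        feasible=feasible,
        predicted_curve=curve,
        windows=windows,
    )


def plan(
    spec: PlanSpec,
    params: ModelParams,
    geometry: CultureGeometry = DEFAULT_GEOMETRY,
    n0: float | None = None,
) -> PlanResult:
    """Full planning workflow: solve C0* analytically, then scan E_in.

    With ``target_fraction`` set (the default), the medium is dosed so that
    the target biomass equals that fraction of the stationary biomass,
    keeping the harvest inside the ``harvest_fractions`` band.
    """
    if n0 is None:
        n0 = CultureCondition.from_od0(1.0, 1.0, geometry=geometry).n0
    n_stationary = (
        spec.target_biomass / spec.target_fraction
        if spec.target_fraction is not None
        else spec.target_biomass
    )
    c0_star = required_c0(n_stationary, n0, params)
    return select_ein(spec, c0_star, params, geometry=geometry, n0=n0)
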