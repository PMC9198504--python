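"""Time integration of the growth models.

Only the biomass ``N`` is integrated; the medium concentration follows
algebraically from the conservation relation ``C(t) = C0 − α (N(t) − N0)``,
so the coupled system never has to be solved as two stiffly linked states.

The integrator is adaptive (LSODA) with relative tolerance 1e-8 and
absolute tolerance of one cell — trajectories span nine orders of
magnitude in ``N``, so a fixed absolute tolerance in OD units would be
meaningless at inoculation density.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core_model import (
    LN10,
    CultureCondition,
    CultureGeometry,
    ModelParams,
    cells_from_od,
    od_from_cells,
)

__all__ = [
    "GrowthCurve",
    "IntegrationError",
    "HorizonError",
    "simulate_full",
    "simulate_mr",
    "stationary_horizon",
    "crossing_times",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1.0  # one cell

#: dN/dt below RATE_FLOOR·mu·N defines "stationary" for horizon purposes.
RATE_FLOOR = 1e-6

_MAX_HORIZON_H = 4.0e6


class IntegrationError(RuntimeError):
    """The ODE solver failed (step-size collapse or similar)."""


class HorizonError(RuntimeError):
    """A requested crossing was not reached within the search horizon."""

    def __init__(self, message: str, achieved_fraction: float | None = None):
        super().__init__(message)
        self.achieved_fraction = achieved_fraction


@dataclass
class GrowthCurve:
    """Simulated trajectory of biomass, medium and optical density.

    ``dense`` holds the solver's dense-output interpolant for ``N(t)``
    (used by the planner for sub-grid crossing times); it is not
    serialized.
    """

    times: np.ndarray
    n_values: np.ndarray
    c_values: np.ndarray
    od_values: np.ndarray
    condition: CultureCondition
    model_tag: Literal["MR", "full"]
    dense: object | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "n_cell": self.n_values,
                "c_rel": self.c_values,
                "od730": self.od_values,
            }
        )

    def to_csv(self, path, params: ModelParams | None = None) -> None:
        """Write the curve as CSV with a ``#``-comment header carrying the
        condition (and optionally the parameters) as JSON."""
        meta = {
            "model": self.model_tag,
            "e_in_uE_per_s": self.condition.e_in,
            "c0": self.condition.c0,
            "n0_cell": self.condition.n0,
            "volume_ml": self.condition.geometry.volume_ml,
            "depth_cm": self.condition.geometry.depth_cm,
        }
        if params is not None:
            meta["params"] = {
                "mu": params.mu,
                "lambda_l": params.lambda_l,
                "gamma_cap": params.gamma_cap,
                "xi_c": params.xi_c,
                "alpha": params.alpha,
                "k_ext": params.k_ext,
            }
        buf = io.StringIO()
        buf.write("# " + json.dumps(meta) + "\n")
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @staticmethod
    def read_csv_frame(path) -> pd.DataFrame:
        """Read back the numeric table of :meth:`to_csv` (metadata ignored)."""
        return pd.read_csv(path, comment="#")


def _make_rhs(
    condition: CultureCondition,
    params: ModelParams,
    model: Literal["MR", "full"],
) -> Callable[[float, np.ndarray], float]:
    """Scalar RHS closure; plain ``math`` ops keep per-call cost low."""
    geom = condition.geometry
    a = params.k_ext * geom.depth_cm / geom.volume_ml  # attenuation per cell
    e_h = condition.e_in_hour
    mu, lam, gamma = params.mu, params.lambda_l, params.gamma_cap
    xi, alpha = params.xi_c, params.alpha
    c0, n0 = condition.c0, condition.n0
    medium_limited = model == "full"

    def rhs(t: float, y) -> list[float]:
        n = y[0]
        if n <= 0.0:
            return [0.0]
        absorbed = -math.expm1(-LN10 * a * n)  # 1 - 10^(-a n)
        l_flux = absorbed * e_h / n
        rate = mu * l_flux / (lam + l_flux) * (1.0 - n / gamma) * n
        if medium_limited:
            c = c0 - alpha * (n - n0)
            if c <= 0.0:
                return [0.0]
            rate *= c / (xi + c)
        return [rate]

    return rhs


def _solve(
    condition: CultureCondition,
    params: ModelParams,
    model: Literal["MR", "full"],
    t_end: float,
    t_eval: np.ndarray | None,
    rtol: float,
    atol: float,
    events=None,
    dense_output: bool = True,
):
    rhs = _make_rhs(condition, params, model)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [condition.n0],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        dense_output=dense_output,
        events=events,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return sol


def _curve_from_solution(
    sol,
    condition: CultureCondition,
    params: ModelParams,
    model: Literal["MR", "full"],
) -> GrowthCurve:
    times = np.asarray(sol.t, dtype=float)
    n = np.asarray(sol.y[0], dtype=float)
    if model == "full":
        c = np.clip(condition.c0 - params.alpha * (n - condition.n0), 0.0, None)
    else:
        c = np.full_like(n, condition.c0)
    od = od_from_cells(n, condition.geometry)
    return GrowthCurve(
        times=times,
        n_values=n,
        c_values=c,
        od_values=od,
        condition=condition,
        model_tag=model,
        dense=sol.sol,
    )


def _simulate(
    condition: CultureCondition,
    params: ModelParams,
    model: Literal["MR", "full"],
    t_end: float | None,
    output_grid: Sequence[float] | float | None,
    rtol: float,
    atol: float,
) -> GrowthCurve:
    if t_end is None:
        t_end = stationary_horizon(condition, params, model=model, rtol=rtol, atol=atol)
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if t_end == 0:
        c0 = condition.c0
        return GrowthCurve(
            times=np.array([0.0]),
            n_values=np.array([condition.n0]),
            c_values=np.array([c0]),
            od_values=np.array([od_from_cells(condition.n0, condition.geometry)]),
            condition=condition,
            model_tag=model,
        )
    if output_grid is None:
        t_eval = None
    elif np.isscalar(output_grid):
        t_eval = np.arange(0.0, t_end + 0.5 * float(output_grid), float(output_grid))
        t_eval = t_eval[t_eval <= t_end]
    else:
        t_eval = np.asarray(output_grid, dtype=float)
        if t_eval.size == 0 or t_eval[0] < 0 or t_eval[-1] > t_end + 1e-9:
            raise ValueError("output_grid must lie within [0, t_end]")
    sol = _solve(condition, params, model, t_end, t_eval, rtol, atol)
    return _curve_from_solution(sol, condition, params, model)


def simulate_full(
    condition: CultureCondition,
    params: ModelParams,
    t_end: float | None = None,
    output_grid: Sequence[float] | float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> GrowthCurve:
    """Integrate the full (light + medium limited) model from (N0, C0).

    Parameters
    ----------
    t_end
        End of integration, h.  ``None`` integrates to a horizon well past
        stationary phase (see :func:`stationary_horizon`).
    output_grid
        ``None`` returns the solver's own steps; a scalar is a grid
        spacing in h; a sequence is an explicit list of output times.
    """
    return _simulate(condition, params, "full", t_end, output_grid, rtol, atol)


def simulate_mr(
    condition: CultureCondition,
    params: ModelParams,
    t_end: float | None = None,
    output_grid: Sequence[float] | float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> GrowthCurve:
    """Integrate the medium-rich model (``r_medium ≡ 1``); C is constant."""
    return _simulate(condition, params, "MR", t_end, output_grid, rtol, atol)


def stationary_horizon(
    condition: CultureCondition,
    params: ModelParams,
    model: Literal["MR", "full"] = "full",
    rate_floor: float = RATE_FLOOR,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Horizon comfortably past stationary phase, h.

    Defined as five times the first time at which the specific growth rate
    drops below ``rate_floor · mu`` — no closed-form transition time exists
    for the coupled light/medium-limited dynamics, so the threshold is
    located by event detection with a doubling search window.
    """
    rhs = _make_rhs(condition, params, model)

    def event(t, y):
        return rhs(t, y)[0] - rate_floor * params.mu * y[0]

    event.terminal = True
    event.direction = -1

    if event(0.0, [condition.n0]) <= 0.0:
        # already (numerically) stationary at t = 0; nothing will happen
        return 1.0

    t_try = 512.0
    while t_try <= _MAX_HORIZON_H:
        sol = _solve(
            condition, params, model, t_try, None, rtol, atol,
            events=event, dense_output=False,
        )
        if sol.t_events[0].size:
            return 5.0 * float(sol.t_events[0][0])
        t_try *= 2.0
    raise HorizonError(
        f"no stationary phase within {_MAX_HORIZON_H} h for e_in={condition.e_in}, c0={condition.c0}"
    )


def crossing_times(
    condition: CultureCondition,
    params: ModelParams,
    targets: Sequence[float],
    model: Literal["MR", "full"] = "full",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> list[float]:
    """First times at which N(t) crosses each target biomass (cells).

    Crossings are located by the solver's event root-finding (sub-grid
    resolution).  Targets must be above ``n0``; a target that is never
    reached raises :class:`HorizonError` carrying the fraction achieved.
    """
    targets = [float(x) for x in targets]
    if any(x <= condition.n0 for x in targets):
        raise ValueError("all targets must exceed the initial biomass n0")

    def make_event(target):
        def event(t, y):
            return y[0] - target

        event.terminal = False
        event.direction = 1
        return event

    events = [make_event(x) for x in targets]
    events[int(np.argmax(targets))].terminal = True

    t_try = 512.0
    while t_try <= _MAX_HORIZON_H:
        sol = _solve(
            condition, params, model, t_try, None, rtol, atol,
            events=events, dense_output=False,
        )
        if all(te.size for te in sol.t_events):
            return [float(te[0]) for te in sol.t_events]
        if sol.t[-1] >= t_try * (1 - 1e-9):
            # ran the whole window without reaching the largest target
            n_end = float(sol.y[0][-1])
            rate = _make_rhs(condition, params, model)(sol.t[-1], [n_end])[0]
            if rate < RATE_FLOOR * params.mu * n_end:
                raise HorizonError(
                    "growth became stationary before reaching the target",
                    achieved_fraction=n_end / max(targets),
                )
        t_try *= 2.0
    raise HorizonError(
        f"targets not reached within {_MAX_HORIZON_H} h",
        achieved_fraction=None,
    )
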