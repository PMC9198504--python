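"""Synthetic growth and light-attenuation data with the statistical
structure the estimation module assumes.

The default :class:`SyntheticSpec` emulates the 16-condition batch
experiment the model was calibrated on: a 4 × 4 matrix of incident light
fluxes (2.92, 1.09, 0.521, 0.274 μE s⁻¹) and initial medium
concentrations (1, 0.5, 0.25, 0.125 of stock), inoculated at OD 0.025 in
200 ml, sampled every 24 h, with each curve run 1.5× past the time it
reaches 99% of its stationary biomass so a plateau is always visible.

The default noise model is multiplicative lognormal — turbidity error
scales with signal — applied to every observation except the t = 0 point,
whose OD is set by the experimenter when inoculating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_model import (
    CultureCondition,
    CultureGeometry,
    DEFAULT_GEOMETRY,
    DEFAULT_PARAMS,
    ModelParams,
)
from .estimation import AttenuationMeasurement, MeasurementSeries
from .planner import max_biomass
from .simulator import crossing_times, simulate_full, simulate_mr

__all__ = [
    "SyntheticSpec",
    "DEFAULT_CONDITION_MATRIX",
    "generate_growth_matrix",
    "generate_attenuation_grid",
    "condition_label",
]

#: (e_in μE s⁻¹, c0) pairs of the reference 4 × 4 experiment.
DEFAULT_CONDITION_MATRIX: tuple[tuple[float, float], ...] = tuple(
    (e_in, c0)
    for e_in in (2.92, 1.09, 0.521, 0.274)
    for c0 in (1.0, 0.5, 0.25, 0.125)
)

NoiseModel = Literal["none", "lognormal", "gaussian"]


def condition_label(e_in: float, c0: float) -> str:
    return f"E{e_in:g}_C{c0:g}"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic growth-curve matrix."""

    true_params: ModelParams = DEFAULT_PARAMS
    geometry: CultureGeometry = DEFAULT_GEOMETRY
    od0: float = 0.025
    condition_matrix: Sequence[tuple[float, float]] = DEFAULT_CONDITION_MATRIX
    sampling_interval: float = 24.0
    horizon: float | None = None  # None: per-condition, 1.5x time to 0.99 N_max
    model: Literal["full", "MR"] = "full"
    noise: NoiseModel = "none"
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.noise != "none" and self.sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise is enabled")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")


def _condition(spec: SyntheticSpec, e_in: float, c0: float) -> CultureCondition:
    return CultureCondition.from_od0(e_in, c0, od0=spec.od0, geometry=spec.geometry)


def _horizon_for(spec: SyntheticSpec, cond: CultureCondition) -> float:
    if spec.horizon is not None:
        return spec.horizon
    n_max = (
        max_biomass(cond, spec.true_params)
        if spec.model == "full"
        else spec.true_params.gamma_cap
    )
    (t99,) = crossing_times(cond, spec.true_params, [0.99 * n_max], model=spec.model)
    return 1.5 * t99


def generate_growth_matrix(spec: SyntheticSpec) -> list[MeasurementSeries]:
    """Simulate every condition in the matrix and sample noisy OD readings.

    Deterministic given ``spec`` (including its seed); conditions are
    processed in matrix order with a single seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    series: list[MeasurementSeries] = []
    for e_in, c0 in spec.condition_matrix:
        cond = _condition(spec, e_in, c0)
        horizon = _horizon_for(spec, cond)
        n_steps = max(int(math.floor(horizon / spec.sampling_interval)), 1)
        times = np.arange(n_steps + 1, dtype=float) * spec.sampling_interval
        run = simulate_full if spec.model == "full" else simulate_mr
        curve = run(cond, spec.true_params, t_end=float(times[-1]), output_grid=times)
        od = curve.od_values.copy()
        if spec.noise != "none" and spec.sigma > 0:
            if spec.noise == "lognormal":
                factors = np.exp(rng.normal(0.0, spec.sigma, size=od.size))
                od[1:] *= factors[1:]
            elif spec.noise == "gaussian":
                offsets = rng.normal(0.0, spec.sigma, size=od.size)
                od[1:] = np.clip(od[1:] + offsets[1:], 1e-6, None)
            else:  # pragma: no cover - guarded by the Literal type
                raise ValueError(f"unknown noise model {spec.noise!r}")
        series.append(
            MeasurementSeries(
                condition=cond,
                times=times,
                od=od,
                label=condition_label(e_in, c0),
            )
        )
    return series


#: Default attenuation grid: four depths up to the flask's light path and
#: five cell densities spanning OD ~0.5 to ~8.
DEFAULT_DEPTHS_CM = (0.925, 1.85, 2.775, 3.7)
DEFAULT_CONCENTRATIONS = (1.505e7, 3.01e7, 6.02e7, 1.204e8, 2.408e8)


def generate_attenuation_grid(
    k_ext: float = DEFAULT_PARAMS.k_ext,
    depths_cm: Sequence[float] = DEFAULT_DEPTHS_CM,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    sigma_log10: float = 0.0,
    seed: int | None = None,
) -> list[AttenuationMeasurement]:
    """Relative-PPFD readings over the full depth × concentration grid.

    ``rel_ppfd = 10^(−K·c·d)``, optionally perturbed by Gaussian noise of
    standard deviation ``sigma_log10`` on the log10 scale.
    """
    if k_ext <= 0:
        raise ValueError("k_ext must be positive")
    if sigma_log10 < 0:
        raise ValueError("sigma_log10 must be non-negative")
    if sigma_log10 > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise is enabled")
    rng = np.random.default_rng(seed)
    out: list[AttenuationMeasurement] = []
    for d in depths_cm:
        for c in concentrations:
            log10_rel = -k_ext * c * d
            if sigma_log10 > 0:
                log10_rel += rng.normal(0.0, sigma_log10)
            out.append(
                AttenuationMeasurement(
                    depth_cm=d,
                    conc_cell_per_ml=c,
                    rel_ppfd=min(10.0**log10_rel, 1.0),
                )
            )
    return out
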