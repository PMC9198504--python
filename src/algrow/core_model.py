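"""Pointwise quantities of the light- and medium-limited logistic growth model.

The model describes batch cultivation of a planktonic microalga in a flask
illuminated from below.  Growth follows a logistic equation whose maximum
specific growth rate is modulated by two Monod-type saturating factors:

* ``r_light(L)`` — a function of the light flux absorbed per cell ``L``,
  obtained from the incident light flux into the culture ``E_in`` via
  base-10 Lambert–Beer attenuation through the culture depth;
* ``r_medium(C)`` — a function of the (dimensionless, relative) medium
  concentration ``C``, which is consumed in proportion to biomass increase.

Units used throughout this module
---------------------------------
========================  =========================================
biomass ``N``             cell
medium ``C``              dimensionless (undiluted stock medium = 1)
time ``t``                h
``mu``                    h⁻¹
``E_in`` (interface)      μE s⁻¹, exactly as a light meter reports it
``E_in`` (rate formulas)  μE h⁻¹ — multiplied by 3600 at ingestion so
                          that fluxes are consistent with ``mu`` in h⁻¹
``L``                     μE h⁻¹ cell⁻¹
``lambda_l``              μE h⁻¹ cell⁻¹
``K`` (``k_ext``)         ml cm⁻¹ cell⁻¹
========================  =========================================

This module is purely algebraic: rates, fluxes and conversions evaluated
at a point.  Time integration lives in :mod:`algrow.simulator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SECONDS_PER_HOUR",
    "CELLS_PER_ML_PER_OD",
    "DRY_WEIGHT_MG_PER_ML_PER_OD",
    "ModelParams",
    "CultureGeometry",
    "CultureCondition",
    "CultureState",
    "ModelConsistencyError",
    "DEFAULT_PARAMS",
    "DEFAULT_GEOMETRY",
    "ein_from_ppfd",
    "od_from_cells",
    "cells_from_od",
    "transmitted_flux",
    "light_flux_per_cell",
    "light_flux_per_cell_limit",
    "r_light",
    "r_medium",
    "specific_growth_rate",
    "medium_from_biomass",
    "dndt_full",
    "dndt_mr",
]

SECONDS_PER_HOUR = 3600.0
LN10 = math.log(10.0)

#: Cell concentration corresponding to one OD730 unit, cell ml⁻¹.
#: Fixed by the calibration pair 99.9e9 cells in 200 ml ↔ OD 16.6.
CELLS_PER_ML_PER_OD = 3.01e7

#: Dry weight per OD730 unit, mg ml⁻¹ (metadata; not used by the model).
DRY_WEIGHT_MG_PER_ML_PER_OD = 0.213

#: Negative medium concentrations beyond this magnitude are treated as
#: genuine domain errors rather than integrator round-off.
C_NEGATIVE_TOL = 1e-9


class ModelConsistencyError(ValueError):
    """A state violates a structural assumption of the model."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the growth model.

    Parameters
    ----------
    mu
        Maximum specific growth rate, h⁻¹.
    lambda_l
        Half-velocity constant for the light flux per cell, μE h⁻¹ cell⁻¹:
        ``r_light(lambda_l) = 1/2``.
    gamma_cap
        Carrying capacity Γ of the logistic brake, cell.
    xi_c
        Half-velocity constant for the relative medium concentration
        (dimensionless): ``r_medium(xi_c) = 1/2``.
    alpha
        Medium consumed per unit biomass increase, cell⁻¹.
    k_ext
        Cell-specific base-10 extinction coefficient K of the Lambert–Beer
        law, ml cm⁻¹ cell⁻¹.
    """

    mu: float
    lambda_l: float
    gamma_cap: float
    xi_c: float
    alpha: float
    k_ext: float

    def __post_init__(self) -> None:
        for name in ("mu", "lambda_l", "gamma_cap", "xi_c", "alpha", "k_ext"):
            _require_positive(name, getattr(self, name))

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class CultureGeometry:
    """Flask geometry: volume, light-path depth, illuminated aperture."""

    volume_ml: float = 200.0
    depth_cm: float = 3.7
    aperture_area_m2: float = 2.826e-3

    def __post_init__(self) -> None:
        _require_positive("volume_ml", self.volume_ml)
        _require_positive("depth_cm", self.depth_cm)
        _require_positive("aperture_area_m2", self.aperture_area_m2)


DEFAULT_GEOMETRY = CultureGeometry()

#: Assessed parameters for the Monoraphidium sp. strain the model was
#: developed on (lambda_l under the hour-consistent flux convention).
DEFAULT_PARAMS = ModelParams(
    mu=0.194,
    lambda_l=1.90e-6,
    gamma_cap=99.9e9,
    xi_c=0.012,
    alpha=8.7e-12,
    k_ext=5.1e-9,
)


@dataclass(frozen=True)
class CultureCondition:
    """Per-run cultivation settings.

    ``e_in`` is stored in μE s⁻¹, the unit a light meter reports; the
    property :attr:`e_in_hour` gives the hour-consistent value used by
    the rate formulas.
    """

    e_in: float
    c0: float
    n0: float
    geometry: CultureGeometry = field(default_factory=CultureGeometry)

    def __post_init__(self) -> None:
        if self.e_in < 0:
            raise ValueError(f"e_in must be non-negative, got {self.e_in!r}")
        if self.c0 < 0:
            raise ValueError(f"c0 must be non-negative, got {self.c0!r}")
        _require_positive("n0", self.n0)

    @property
    def e_in_hour(self) -> float:
        """Incident light flux in μE h⁻¹."""
        return self.e_in * SECONDS_PER_HOUR

    @property
    def od0(self) -> float:
        return od_from_cells(self.n0, self.geometry)

    @classmethod
    def from_od0(
        cls,
        e_in: float,
        c0: float,
        od0: float = 0.025,
        geometry: CultureGeometry = DEFAULT_GEOMETRY,
    ) -> "CultureCondition":
        """Build a condition from an initial optical density."""
        return cls(e_in=e_in, c0=c0, n0=cells_from_od(od0, geometry), geometry=geometry)


@dataclass(frozen=True)
class CultureState:
    """Instantaneous culture state (t in h, n in cell, c dimensionless)."""

    t: float
    n: float
    c: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be non-negative")
        _require_positive("n", self.n)
        if self.c < -C_NEGATIVE_TOL:
            raise ValueError(f"c must be non-negative (got {self.c!r})")


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def ein_from_ppfd(ppfd: float, area_m2: float) -> float:
    """Incident light flux into culture, μE s⁻¹, from PPFD × aperture area.

    ``ppfd`` is the photosynthetic photon flux density in μE m⁻² s⁻¹ and
    ``area_m2`` the regulated illuminated area in m².
    """
    if ppfd < 0:
        raise ValueError("ppfd must be non-negative")
    _require_positive("area_m2", area_m2)
    return ppfd * area_m2


def od_from_cells(n, geometry: CultureGeometry = DEFAULT_GEOMETRY):
    """Convert biomass (cell) to OD730: ``(n / V) / CELLS_PER_ML_PER_OD``."""
    if np.any(np.asarray(n) < 0):
        raise ValueError("biomass must be non-negative")
    return (n / geometry.volume_ml) / CELLS_PER_ML_PER_OD


def cells_from_od(od, geometry: CultureGeometry = DEFAULT_GEOMETRY):
    """Convert OD730 to biomass in cells; inverse of :func:`od_from_cells`."""
    if np.any(np.asarray(od) < 0):
        raise ValueError("OD must be non-negative")
    return od * CELLS_PER_ML_PER_OD * geometry.volume_ml


# ---------------------------------------------------------------------------
# light
# ---------------------------------------------------------------------------

def transmitted_flux(n, e_in, params: ModelParams, geometry: CultureGeometry):
    """Light flux transmitted through the culture (same units as ``e_in``).

    Lambert–Beer attenuation in base 10:
    ``E_out = E_in · 10^(−K · (N/V) · D)``.
    """
    if np.any(np.asarray(n) < 0):
        raise ValueError("biomass must be non-negative")
    exponent = params.k_ext * (np.asarray(n, dtype=float) / geometry.volume_ml) * geometry.depth_cm
    return e_in * 10.0 ** (-exponent)


def light_flux_per_cell(n, e_in_hour, params: ModelParams, geometry: CultureGeometry):
    """Absorbed light flux per cell L, μE h⁻¹ cell⁻¹.

    ``L = (E_in − E_out) / N``; ``e_in_hour`` must already be in μE h⁻¹
    (see :attr:`CultureCondition.e_in_hour`).  Strictly decreasing in ``n``
    and bounded above by the dilute-culture limit
    :func:`light_flux_per_cell_limit`.
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr <= 0):
        raise ValueError("biomass must be strictly positive; use light_flux_per_cell_limit for n -> 0")
    exponent = params.k_ext * (n_arr / geometry.volume_ml) * geometry.depth_cm
    return -np.expm1(-LN10 * exponent) * e_in_hour / n_arr


def light_flux_per_cell_limit(e_in_hour, params: ModelParams, geometry: CultureGeometry):
    """Dilute-culture (n → 0⁺) limit of the light flux per cell.

    First-order expansion of ``1 − 10^(−K n D / V)`` gives
    ``L → E_in · ln(10) · K · D / V``.
    """
    return e_in_hour * LN10 * params.k_ext * geometry.depth_cm / geometry.volume_ml


# ---------------------------------------------------------------------------
# Monod factors and growth rates
# ---------------------------------------------------------------------------

def r_light(l_flux, params: ModelParams):
    """Light limitation factor ``L / (lambda_l + L)`` ∈ [0, 1)."""
    if np.any(np.asarray(l_flux) < 0):
        raise ValueError("light flux per cell must be non-negative")
    return l_flux / (params.lambda_l + l_flux)


def r_medium(c, params: ModelParams):
    """Medium limitation factor ``C / (xi_c + C)`` ∈ [0, 1).

    Slightly negative ``c`` from integrator round-off (within
    ``C_NEGATIVE_TOL``) is clamped to 0.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < -C_NEGATIVE_TOL):
        raise ValueError("medium concentration must be non-negative")
    c_arr = np.clip(c_arr, 0.0, None)
    out = c_arr / (params.xi_c + c_arr)
    return float(out) if np.isscalar(c) else out


def specific_growth_rate(l_flux, c, params: ModelParams):
    """``r(L, C) = mu · r_light(L) · r_medium(C)``, h⁻¹, bounded by mu."""
    return params.mu * r_light(l_flux, params) * r_medium(c, params)


def medium_from_biomass(n, condition: CultureCondition, params: ModelParams):
    """Medium remaining after growing from n0 to n: ``C = C0 − α (N − N0)``.

    May be negative if growth exceeded the medium budget; callers that
    evaluate rates should clamp at 0 (``r_medium`` does so for round-off
    level undershoot only).
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < condition.n0 * (1.0 - 1e-12)):
        raise ValueError("biomass below its initial value n0")
    out = condition.c0 - params.alpha * (n_arr - condition.n0)
    return float(out) if np.isscalar(n) else out


# ---------------------------------------------------------------------------
# ODE right-hand sides (pointwise)
# ---------------------------------------------------------------------------

def _check_n_vs_gamma(n: float, params: ModelParams) -> None:
    if n > params.gamma_cap * (1.0 + 1e-6):
        raise ModelConsistencyError(
            f"biomass {n!r} exceeds the carrying capacity {params.gamma_cap!r}"
        )


def dndt_full(state: CultureState, condition: CultureCondition, params: ModelParams) -> float:
    """Growth rate dN/dt of the full (light + medium limited) model, cell h⁻¹.

    ``dN/dt = mu · r_medium(C) · r_light(L(N)) · (1 − N/Γ) · N``.
    Vanishes when the medium is depleted (C = 0) or N reaches Γ.
    """
    _check_n_vs_gamma(state.n, params)
    l_flux = light_flux_per_cell(state.n, condition.e_in_hour, params, condition.geometry)
    rate = specific_growth_rate(l_flux, max(state.c, 0.0), params)
    return rate * (1.0 - state.n / params.gamma_cap) * state.n


def dndt_mr(state: CultureState, condition: CultureCondition, params: ModelParams) -> float:
    """Growth rate of the medium-rich (MR) model: ``r_medium ≡ 1``.

    Valid while nutrients are in excess; only light absorption and the
    logistic brake limit growth.
    """
    _check_n_vs_gamma(state.n, params)
    l_flux = light_flux_per_cell(state.n, condition.e_in_hour, params, condition.geometry)
    return params.mu * r_light(l_flux, params) * (1.0 - state.n / params.gamma_cap) * state.n
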