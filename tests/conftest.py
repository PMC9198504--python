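"""Shared fixtures: reference parameters and synthetic datasets.

Expensive artefacts (the clean 16-condition matrix, the step-1 and step-2
fits on it, the stationary-phase simulations) are session-scoped so the
estimation, planner and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from algrow.core_model import (
    CultureCondition,
    DEFAULT_GEOMETRY,
    DEFAULT_PARAMS,
    cells_from_od,
)
from algrow.estimation import fit_full_step, fit_mr_step
from algrow.simulator import simulate_full
from algrow.synthetic_data import (
    DEFAULT_CONDITION_MATRIX,
    SyntheticSpec,
    generate_growth_matrix,
)

EIN_PANEL = (2.92, 1.09, 0.521, 0.274)
C0_PANEL = (1.0, 0.5, 0.25, 0.125)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def n0(geometry):
    return float(cells_from_od(0.025, geometry))


@pytest.fixture(scope="session")
def reference_condition(n0, geometry):
    """Brightest light, undiluted medium."""
    return CultureCondition(e_in=2.92, c0=1.0, n0=n0, geometry=geometry)


@pytest.fixture(scope="session")
def clean_matrix():
    """Noise-free full-model growth matrix over all 16 conditions."""
    return generate_growth_matrix(SyntheticSpec())


@pytest.fixture(scope="session")
def rich_panel(clean_matrix):
    """The four undiluted-medium (C0 = 1) series of the clean matrix."""
    return [s for s in clean_matrix if s.condition.c0 == 1.0]


@pytest.fixture(scope="session")
def mr_panel():
    """Noise-free panel generated by the MR model itself (step-1 oracle)."""
    spec = SyntheticSpec(
        condition_matrix=[(e, 1.0) for e in EIN_PANEL], model="MR"
    )
    return generate_growth_matrix(spec)


@pytest.fixture(scope="session")
def mr_fit_clean(rich_panel, geometry, params):
    """Step-1 fit on the clean full-model C0 = 1 panel."""
    return fit_mr_step(rich_panel, geometry, k_ext=params.k_ext, seed=11)


@pytest.fixture(scope="session")
def full_fit_truth(clean_matrix, geometry, params):
    """Step-2 fit on the clean matrix with step-1 parameters at truth."""
    mr_truth = params.replace(xi_c=1.0, alpha=1e-30)
    return fit_full_step(clean_matrix, mr_truth, geometry, seed=11)


@pytest.fixture(scope="session")
def stationary_curves(params, n0, geometry):
    """Full-model simulations to past stationary phase, all 16 conditions."""
    curves = {}
    for e_in, c0 in DEFAULT_CONDITION_MATRIX:
        cond = CultureCondition(e_in=e_in, c0=c0, n0=n0, geometry=geometry)
        curves[(e_in, c0)] = simulate_full(cond, params)
    return curves
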