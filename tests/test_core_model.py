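"""Pointwise model quantities: conversions, fluxes, Monod factors, rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algrow.core_model import (
    CELLS_PER_ML_PER_OD,
    CultureCondition,
    CultureGeometry,
    CultureState,
    DEFAULT_GEOMETRY,
    DEFAULT_PARAMS,
    ModelConsistencyError,
    ModelParams,
    cells_from_od,
    dndt_full,
    dndt_mr,
    ein_from_ppfd,
    light_flux_per_cell,
    light_flux_per_cell_limit,
    medium_from_biomass,
    od_from_cells,
    r_light,
    r_medium,
    specific_growth_rate,
    transmitted_flux,
)

P = DEFAULT_PARAMS
G = DEFAULT_GEOMETRY
AREA = 2.826e-3

hsettings = settings(max_examples=60, deadline=None, derandomize=True)


class TestConversions:
    @pytest.mark.parametrize(
        "ppfd, expected",
        [(1034, 2.922), (386.7, 1.0928), (184.8, 0.52224), (96.8, 0.27356)],
    )
    def test_incident_flux_from_ppfd(self, ppfd, expected):
        assert ein_from_ppfd(ppfd, AREA) == pytest.approx(expected, rel=1e-4)

    def test_zero_ppfd_gives_zero_flux(self):
        assert ein_from_ppfd(0.0, AREA) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ein_from_ppfd(-1.0, AREA)
        with pytest.raises(ValueError):
            ein_from_ppfd(10.0, 0.0)

    def test_carrying_capacity_od(self):
        # 99.9e9 cells in 200 ml correspond to OD 16.6
        assert od_from_cells(99.9e9, G) == pytest.approx(16.6, abs=0.05)

    def test_unit_od_cell_count(self):
        assert od_from_cells(6.02e9, G) == pytest.approx(1.00, rel=1e-3)

    def test_od_zero(self):
        assert od_from_cells(0.0, G) == 0.0

    @given(st.floats(min_value=1e-3, max_value=50.0))
    @hsettings
    def test_od_cells_round_trip(self, od):
        assert cells_from_od(od_from_cells(cells_from_od(od, G), G), G) == pytest.approx(
            cells_from_od(od, G), rel=1e-12
        )

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            od_from_cells(-1.0, G)


class TestLight:
    def test_empty_culture_transmits_everything(self):
        assert transmitted_flux(0.0, 5.0, P, G) == 5.0

    def test_attenuation_exponent(self):
        # K * (N/V) * D = 5.1e-9 * (1.505e8/200) * 3.7 = 0.0142
        expected = 3.0 * 10 ** (-0.0142)
        assert transmitted_flux(1.505e8, 3.0, P, G) == pytest.approx(expected, rel=1e-3)

    def test_dense_culture_absorbs_everything(self):
        assert transmitted_flux(1e15, 3.0, P, G) == pytest.approx(0.0, abs=1e-12)

    def test_light_per_cell_reference_value(self):
        # n = 1.505e8 cells, E_in = 2.92 uE/s in hour units
        e_h = 2.92 * 3600.0
        assert light_flux_per_cell(1.505e8, e_h, P, G) == pytest.approx(2.2468e-6, rel=1e-4)

    def test_light_per_cell_dilute_limit(self):
        e_h = 2.92 * 3600.0
        limit = light_flux_per_cell_limit(e_h, P, G)
        assert limit == pytest.approx(e_h * math.log(10) * P.k_ext * G.depth_cm / G.volume_ml)
        # approached from below as n -> 0
        assert light_flux_per_cell(1.0, e_h, P, G) == pytest.approx(limit, rel=1e-9)
        assert light_flux_per_cell(1.0, e_h, P, G) < limit

    def test_light_per_cell_full_absorption_regime(self):
        e_h = 2.92 * 3600.0
        n = 1e14
        assert light_flux_per_cell(n, e_h, P, G) == pytest.approx(e_h / n, rel=1e-6)

    def test_zero_biomass_is_domain_error(self):
        with pytest.raises(ValueError):
            light_flux_per_cell(0.0, 1.0, P, G)

    @given(
        st.floats(min_value=1e2, max_value=1e12),
        st.floats(min_value=1.01, max_value=100.0),
    )
    @hsettings
    def test_light_per_cell_strictly_decreasing(self, n1, factor):
        e_h = 1.09 * 3600.0
        n2 = n1 * factor
        assert light_flux_per_cell(n2, e_h, P, G) < light_flux_per_cell(n1, e_h, P, G)

    @given(st.floats(min_value=1e2, max_value=1e12))
    @hsettings
    def test_flux_bookkeeping(self, n):
        """Absorbed plus transmitted flux equals the incident flux."""
        e_h = 0.521 * 3600.0
        e_out = transmitted_flux(n, e_h, P, G)
        l_flux = light_flux_per_cell(n, e_h, P, G)
        assert 0 <= e_out <= e_h
        assert e_out + n * l_flux == pytest.approx(e_h, rel=1e-12)


class TestMonodFactors:
    def test_half_velocity_identities(self):
        assert r_light(P.lambda_l, P) == pytest.approx(0.5, rel=1e-15)
        assert r_medium(P.xi_c, P) == pytest.approx(0.5, rel=1e-15)

    def test_r_light_examples(self):
        assert r_light(0.0, P) == 0.0
        assert r_light(3 * P.lambda_l, P) == pytest.approx(0.75)

    def test_r_medium_examples(self):
        assert r_medium(0.0, P) == 0.0
        assert r_medium(1.0, P) == pytest.approx(1.0 / 1.012, rel=1e-12)

    def test_r_medium_clamps_solver_undershoot(self):
        assert r_medium(-1e-12, P) == 0.0
        with pytest.raises(ValueError):
            r_medium(-1e-3, P)

    @given(st.floats(min_value=0, max_value=100.0), st.floats(min_value=1e-3, max_value=100.0))
    @hsettings
    def test_monod_factors_bounded_and_increasing(self, k, dk):
        # inputs scaled by each factor's half-velocity constant so the
        # increment is resolvable in double precision
        for f, half in ((r_light, P.lambda_l), (r_medium, P.xi_c)):
            lo, hi = f(k * half, P), f((k + dk) * half, P)
            assert 0.0 <= lo < 1.0
            assert hi > lo

    def test_specific_growth_rate_caps_at_mu(self):
        assert specific_growth_rate(1e6, 1e6, P) == pytest.approx(P.mu, rel=1e-5)
        assert specific_growth_rate(0.0, 1.0, P) == 0.0
        assert specific_growth_rate(P.lambda_l, P.xi_c, P) == pytest.approx(P.mu / 4)

    @given(st.floats(min_value=0, max_value=1e2), st.floats(min_value=0, max_value=1e2))
    @hsettings
    def test_specific_growth_rate_bounded(self, l_flux, c):
        assert 0.0 <= specific_growth_rate(l_flux, c, P) <= P.mu


class TestMediumBudget:
    def _cond(self, c0):
        return CultureCondition(e_in=1.0, c0=c0, n0=1.505e8, geometry=G)

    def test_initial_state(self):
        assert medium_from_biomass(1.505e8, self._cond(0.7), P) == pytest.approx(0.7)

    def test_depletion_point(self):
        cond = self._cond(0.5)
        n_dep = cond.n0 + 0.5 / P.alpha
        assert medium_from_biomass(n_dep, cond, P) == pytest.approx(0.0, abs=1e-12)

    def test_intermediate_value(self):
        assert medium_from_biomass(5e10, self._cond(1.0), P) == pytest.approx(0.566, rel=1e-3)

    def test_biomass_below_n0_rejected(self):
        with pytest.raises(ValueError):
            medium_from_biomass(1e8, self._cond(1.0), P)


class TestGrowthRates:
    def _cond(self, e_in=2.92, c0=1.0):
        return CultureCondition(e_in=e_in, c0=c0, n0=1.505e8, geometry=G)

    def test_logistic_brake_at_capacity(self):
        state = CultureState(t=0.0, n=P.gamma_cap, c=1.0)
        assert dndt_full(state, self._cond(), P) == pytest.approx(0.0, abs=1e-3)
        assert dndt_mr(state, self._cond(), P) == pytest.approx(0.0, abs=1e-3)

    def test_depleted_medium_stops_growth(self):
        state = CultureState(t=10.0, n=1e10, c=0.0)
        assert dndt_full(state, self._cond(), P) == 0.0

    def test_biomass_above_capacity_is_inconsistent(self):
        state = CultureState(t=0.0, n=1.01 * P.gamma_cap, c=1.0)
        with pytest.raises(ModelConsistencyError):
            dndt_full(state, self._cond(), P)

    def test_reduces_to_classic_logistic(self):
        # lambda_l, xi_c -> 0 removes both Monod brakes
        p = P.replace(lambda_l=1e-300, xi_c=1e-300)
        n = 1e9
        state = CultureState(t=0.0, n=n, c=1.0)
        expected = p.mu * (1 - n / p.gamma_cap) * n
        assert dndt_full(state, self._cond(), p) == pytest.approx(expected, rel=1e-12)

    def test_mr_equals_full_when_medium_saturates(self):
        p = P.replace(xi_c=1e-300)
        state = CultureState(t=5.0, n=3e9, c=0.8)
        assert dndt_mr(state, self._cond(), p) == pytest.approx(
            dndt_full(state, self._cond(), p), rel=1e-12
        )

    def test_mr_linear_light_regime(self):
        # lambda_l >> L: rate ~ mu * (L / lambda_l) * n for small n
        p = P.replace(lambda_l=1.0)
        cond = self._cond()
        n = 1e6
        state = CultureState(t=0.0, n=n, c=1.0)
        l_flux = light_flux_per_cell(n, cond.e_in_hour, p, G)
        assert dndt_mr(state, cond, p) == pytest.approx(p.mu * l_flux * n, rel=1e-4)


class TestValidation:
    def test_params_must_be_positive(self):
        with pytest.raises(ValueError):
            ModelParams(mu=0.0, lambda_l=1e-6, gamma_cap=1e11, xi_c=0.01, alpha=1e-12, k_ext=5e-9)
        with pytest.raises(ValueError):
            P.replace(gamma_cap=math.inf)

    def test_condition_invariants(self):
        with pytest.raises(ValueError):
            CultureCondition(e_in=-0.1, c0=1.0, n0=1e8)
        with pytest.raises(ValueError):
            CultureCondition(e_in=1.0, c0=-0.1, n0=1e8)
        with pytest.raises(ValueError):
            CultureCondition(e_in=1.0, c0=1.0, n0=0.0)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            CultureGeometry(volume_ml=-1.0)

    def test_default_inoculum(self):
        cond = CultureCondition.from_od0(2.92, 1.0)
        assert cond.n0 == pytest.approx(0.025 * CELLS_PER_ML_PER_OD * 200.0)
        assert cond.od0 == pytest.approx(0.025)
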