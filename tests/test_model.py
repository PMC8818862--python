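"""Flux laws: channel, pump and cotransporter fluxes, potentials, derivatives."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pumpleak import (
    RT_F,
    CellState,
    Medium,
    ParameterError,
    TransportParams,
    channel_fluxes,
    content_derivatives,
    cotransporter_fluxes,
    electrochemical_potentials,
    flux_table,
    pump_fluxes,
    solve_potential,
)
from pumpleak.model import IONS, PATHWAYS
from pumpleak.dynamics import apply_medium_jump

U_REST = -45.0 / RT_F  # dimensionless resting potential of the full set


class TestChannelFluxes:
    @pytest.mark.parametrize(
        "p,u,ci,co,valence,influx,efflux",
        [
            # K+ channel at the full-set resting potential (printed to 4 dp,
            # allow for the rounding of the printed potential)
            (0.0115, U_REST, 147.0, 5.8, 1, 0.1381, -0.6477),
            # Na+ channel, same state
            (0.0017, U_REST, 38.0, 140.0, 1, 0.4927, -0.0248),
            # Cl- channel (anion decomposition)
            (0.011, U_REST, 45.0, 116.0, -1, 0.4889, -1.0246),
        ],
    )
    def test_resting_decomposition(self, p, u, ci, co, valence, influx, efflux):
        fl = channel_fluxes(p, u, ci, co, valence=valence)
        assert fl.influx == pytest.approx(influx, abs=2e-3)
        assert fl.efflux == pytest.approx(efflux, abs=2e-3)

    def test_sodium_net_flux_at_rest(self):
        fl = channel_fluxes(0.0017, U_REST, 38.0, 140.0, valence=1)
        assert fl.net == pytest.approx(0.4679, abs=2e-3)

    def test_zero_gradient_zero_potential(self):
        assert channel_fluxes(0.123, 0.0, 88.0, 88.0).net == pytest.approx(0.0, abs=1e-15)

    def test_fick_limit_at_small_potential(self):
        # u -> 0: net tends to p*(co - ci); series branch vs direct branch agree
        p, ci, co = 0.01, 45.0, 116.0
        for valence in (1, -1):
            tiny = channel_fluxes(p, 1e-6, ci, co, valence=valence).net
            direct = channel_fluxes(p, 2e-4, ci, co, valence=valence).net
            assert tiny == pytest.approx(p * (co - ci), rel=1e-5)
            assert direct == pytest.approx(tiny, rel=1e-3)
            series = channel_fluxes(p, 9.9e-5, ci, co, valence=valence).net
            assert series == pytest.approx(direct, rel=1e-3)

    @given(
        p=st.floats(1e-6, 1.0),
        u=st.floats(-8.0, 4.0),
        ci=st.floats(0.1, 500.0),
        co=st.floats(0.1, 500.0),
        valence=st.sampled_from([1, -1]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_unidirectional_decomposition(self, p, u, ci, co, valence):
        fl = channel_fluxes(p, u, ci, co, valence=valence)
        assert fl.influx >= 0.0
        assert fl.efflux <= 0.0
        assert fl.net == pytest.approx(fl.influx + fl.efflux, abs=1e-12)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ParameterError):
            channel_fluxes(-0.01, -1.0, 10.0, 10.0)
        with pytest.raises(ParameterError):
            channel_fluxes(0.01, -1.0, -10.0, 10.0)


class TestPumpFluxes:
    @pytest.mark.parametrize(
        "beta,nai,gamma,na_eff,k_in",
        [
            (0.039, 38.0, 1.5, -1.4820, 0.9880),
            (0.0, 38.0, 1.5, 0.0, 0.0),
            (0.039, 91.0, 1.5, -3.549, 2.366),
        ],
    )
    def test_stoichiometry(self, beta, nai, gamma, na_eff, k_in):
        out = pump_fluxes(beta, nai, gamma)
        assert out[0] == pytest.approx(na_eff, abs=5e-4)
        assert out[1] == pytest.approx(k_in, abs=5e-4)

    def test_gamma_zero_rejected(self):
        with pytest.raises(ParameterError):
            pump_fluxes(0.039, 38.0, gamma=0.0)


class TestCotransporterFluxes:
    def test_resting_unidirectionals(self, resting_state, normal_medium, full_params):
        cot = cotransporter_fluxes(full_params, normal_medium, resting_state)
        assert cot["nc"].influx == pytest.approx(1.1368, abs=1e-4)
        assert cot["nc"].efflux == pytest.approx(-0.1197, abs=1e-4)
        assert cot["nkcc"].influx == pytest.approx(0.0874, abs=1e-4)
        assert cot["nkcc"].efflux == pytest.approx(-0.0905, abs=1e-4)
        assert cot["kc"].influx == pytest.approx(0.0538, abs=1e-4)

    def test_equilibrium_products_zero_net(self, normal_medium):
        # internal products equal to external ones -> no net cotransport
        m = normal_medium
        state = CellState.from_concentrations(m.na0, m.k0, m.cl0, Medium(m.na0, m.k0, m.cl0, 60.0))
        params = TransportParams(0.0, 0.0, 0.0, 0.0, inc=1e-4, ikc=2e-4, inkcc=5e-9)
        cot = cotransporter_fluxes(params, m, state)
        for pathway in ("nc", "kc", "nkcc"):
            assert cot[pathway].net == pytest.approx(0.0, abs=1e-12)


class TestElectrochemicalPotentials:
    def test_resting_driving_forces(self, resting_state, normal_medium):
        mu = electrochemical_potentials(resting_state, normal_medium, -45.0)
        assert mu.mu_na == pytest.approx(-79.9, abs=0.1)
        assert mu.mu_k == pytest.approx(41.3, abs=0.1)
        assert mu.mu_cl == pytest.approx(19.8, abs=0.1)
        # cotransporter driving forces are sums over the carried ions
        assert mu.mu_nc == pytest.approx(mu.mu_na + mu.mu_cl, abs=1e-12)
        assert mu.mu_kc == pytest.approx(mu.mu_k + mu.mu_cl, abs=1e-12)
        assert mu.mu_nkcc == pytest.approx(mu.mu_na + mu.mu_k + 2 * mu.mu_cl, abs=1e-12)

    def test_nkcc_near_equilibrium_at_rest(self, resting_state, normal_medium):
        # in the normal medium the NKCC driving force is close to zero
        mu = electrochemical_potentials(resting_state, normal_medium, -45.0)
        assert abs(mu.mu_nkcc) < 2.0

    def test_all_zero_at_equilibrium(self):
        m = Medium(100.0, 100.0, 100.0, 10.0)
        s = CellState.from_concentrations(100.0, 100.0, 100.0, Medium(100.0, 100.0, 100.0, 110.0))
        mu = electrochemical_potentials(s, m, 0.0)
        assert all(abs(x) < 1e-12 for x in mu)


class TestContentDerivatives:
    def test_resting_state_is_balanced(self, resting_state, full_params, normal_medium, resting_u):
        dq = content_derivatives(resting_state, full_params, normal_medium, resting_u)
        assert all(abs(d) < 0.01 for d in dq)

    def test_all_rates_zero(self, resting_state, normal_medium):
        p = TransportParams(0.0, 0.0, 0.0, 0.0)
        assert content_derivatives(resting_state, p, normal_medium, -1.0) == (0.0, 0.0, 0.0)

    def test_chloride_enters_after_nacl_jump(
        self, resting_state, full_params, nacl_medium
    ):
        post = apply_medium_jump(resting_state, nacl_medium)
        u = solve_potential(post, full_params, nacl_medium).u
        tab = flux_table(post, full_params, nacl_medium, u)
        assert tab.total_net("cl") > 0.0


class TestFluxTable:
    def test_total_equals_pathway_sum(self, resting_state, full_params, normal_medium, resting_u):
        tab = flux_table(resting_state, full_params, normal_medium, resting_u)
        for ion in IONS:
            total = sum(tab.net(ion, p) for p in PATHWAYS)
            assert tab.total_net(ion) == pytest.approx(total, abs=1e-12)

    def test_cotransport_stoichiometry(self, resting_state, full_params, normal_medium, resting_u):
        tab = flux_table(resting_state, full_params, normal_medium, resting_u)
        assert tab.net("na", "nc") == tab.net("cl", "nc")
        assert tab.net("k", "kc") == tab.net("cl", "kc")
        assert tab.net("na", "nkcc") == tab.net("k", "nkcc")
        assert tab.net("na", "nkcc") == pytest.approx(0.5 * tab.net("cl", "nkcc"), abs=1e-15)

    def test_cotransporters_carry_no_charge(self, resting_state, full_params, normal_medium, resting_u):
        # per-pathway charge flux: cations in minus anions in
        tab = flux_table(resting_state, full_params, normal_medium, resting_u)
        for pathway in ("nc", "kc", "nkcc"):
            charge = tab.net("na", pathway) + tab.net("k", pathway) - tab.net("cl", pathway)
            assert charge == pytest.approx(0.0, abs=1e-15)

    def test_signs(self, resting_state, full_params, normal_medium, resting_u):
        tab = flux_table(resting_state, full_params, normal_medium, resting_u)
        for key, fl in tab.fluxes.items():
            assert fl.influx >= 0.0, key
            assert fl.efflux <= 0.0, key


class TestStateTypes:
    def test_concentration_accessors(self, resting_state):
        assert resting_state.na == pytest.approx(38.0)
        assert resting_state.k == pytest.approx(147.0)
        assert resting_state.cl == pytest.approx(45.0)
        assert resting_state.a_conc == pytest.approx(80.0)

    def test_resting_state_consistent(self, resting_state):
        assert resting_state.is_consistent()

    def test_medium_osmolarity(self, normal_medium, nacl_medium, sucrose_medium):
        assert normal_medium.osmolarity() == pytest.approx(310.0)
        assert nacl_medium.osmolarity() == pytest.approx(510.0)
        assert sucrose_medium.osmolarity() == pytest.approx(490.0)

    def test_invalid_states_rejected(self):
        with pytest.raises(ParameterError):
            Medium(-1.0, 5.8, 116.0)
        with pytest.raises(ParameterError):
            CellState(qna=100.0, qk=100.0, qcl=50.0, z=-1.0, v=0.0)
        with pytest.raises(ParameterError):
            TransportParams(pna=-0.1, pk=0.0, pcl=0.0, beta=0.0)

    def test_beta_decay_clamps_at_zero(self):
        p = TransportParams(0.001, 0.01, 0.01, beta=0.04, kb=0.01)
        assert p.beta_at(0.0) == pytest.approx(0.04)
        assert p.beta_at(50.0) == pytest.approx(0.02)
        assert p.beta_at(200.0) == 0.0

    def test_scaled_rejects_unknown_keys(self, full_params):
        with pytest.raises(ParameterError):
            full_params.scaled({"pmg": 2.0})
        scaled = full_params.scaled({"inc": 3.0, "pna": 0.5})
        assert scaled.inc == pytest.approx(3.0 * full_params.inc)
        assert scaled.pna == pytest.approx(0.5 * full_params.pna)

    @given(
        na=st.floats(1.0, 200.0),
        k=st.floats(1.0, 250.0),
        cl=st.floats(1.0, 150.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_from_concentrations_closes_both_balances(self, na, k, cl):
        medium = Medium(140.0, 5.8, 116.0, 48.2)
        if medium.osmolarity() - (na + k + cl) <= 1.0:
            return
        s = CellState.from_concentrations(na, k, cl, medium)
        assert s.is_consistent(1e-12)
        assert s.osmolarity() == pytest.approx(medium.osmolarity(), rel=1e-12)
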