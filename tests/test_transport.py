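"""Transport thermodynamics, speciation and the reduced network model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rubberfit.plausibility import DomainError, round_to_sig
from rubberfit.transport import (
    Condition,
    ToyNetworkParams,
    TransportPhysics,
    accumulation_factor_active,
    accumulation_factor_passive,
    fluxes,
    futile_cycle_atp_equivalent,
    glnk_knockout,
    observables,
    simulate,
    speciate,
    steady_state,
    toy_rhs,
)

PARAMS = ToyNetworkParams(
    vmax_amtb=100.0, km_amtb=0.01, p_diff=50.0, vmax_gs=40.0, km_gs=0.1,
    k_glnk=0.02, n_glnk=2.0, mu_max=0.4, k_growth=0.5, k_dil=10.0,
)

ACTIVE = TransportPhysics(mode="active", delta_psi=-150.0, temperature=310.0,
                          ph_ext=7.0, ph_int=7.6)
PASSIVE = TransportPhysics(mode="passive", delta_psi=-150.0, temperature=310.0,
                           ph_ext=7.0, ph_int=7.6)


def make_condition(physics=ACTIVE, nhx_ext=1.0, init=None, knockout=False):
    return Condition(
        condition_id="test", physics=physics, nhx_ext=nhx_ext,
        initial_state=init or {"nhx_int": 0.05, "gln": 1.0, "glu": 40.0},
        glnk_knockout=knockout,
    )


class TestAccumulationFactor:
    @pytest.mark.parametrize("temp,expected", [(310.0, 275.0), (303.0, 313.0)])
    def test_active_at_minus_150_mv(self, temp, expected):
        assert round_to_sig(accumulation_factor_active(-150.0, temp), 3) == expected

    def test_active_vanishing_potential(self):
        assert accumulation_factor_active(0.0, 310.0) == 1.0

    def test_active_rejects_nonpositive_temperature(self):
        with pytest.raises(DomainError):
            accumulation_factor_active(-150.0, 0.0)

    @given(st.floats(-300, 300), st.floats(250, 350))
    @settings(max_examples=50, derandomize=True)
    def test_active_sign_symmetry(self, psi, temp):
        prod = accumulation_factor_active(psi, temp) * accumulation_factor_active(-psi, temp)
        assert prod == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("ph_ext,expected", [(7.0, 0.25), (7.4, 0.63)])
    def test_passive_at_internal_ph_76(self, ph_ext, expected):
        assert round_to_sig(accumulation_factor_passive(ph_ext, 7.6), 2) == expected

    def test_passive_equal_ph(self):
        assert accumulation_factor_passive(7.2, 7.2) == 1.0

    @given(st.floats(5, 9), st.floats(5, 9), st.floats(5, 9))
    @settings(max_examples=50, derandomize=True)
    def test_passive_multiplicative_in_ph_difference(self, a, b, c):
        lhs = accumulation_factor_passive(a, b) * accumulation_factor_passive(b, c)
        assert lhs == pytest.approx(accumulation_factor_passive(a, c), rel=1e-9)


class TestSpeciation:
    def test_equal_halves_at_pka(self):
        nh4, nh3 = speciate(8.0, 9.25, 9.25)
        assert nh4 == pytest.approx(4.0) and nh3 == pytest.approx(4.0)

    def test_closed_form_two_units_below_pka(self):
        nh4, nh3 = speciate(100.0, 7.25, 9.25)
        assert nh3 == pytest.approx(100.0 / 101.0, rel=1e-12)

    def test_zero_total(self):
        assert speciate(0.0, 7.0) == (0.0, 0.0)

    def test_negative_total_rejected(self):
        with pytest.raises(DomainError):
            speciate(-1.0, 7.0)

    @given(st.floats(1e-9, 100), st.floats(5, 10))
    @settings(max_examples=50, derandomize=True)
    def test_species_sum_and_ratio(self, total, ph):
        nh4, nh3 = speciate(total, ph)
        assert nh4 + nh3 == pytest.approx(total, rel=1e-12, abs=1e-15)
        if nh4 > 0:
            assert nh3 / nh4 == pytest.approx(10 ** (ph - 9.25), rel=1e-9)


class TestToyRhs:
    def test_amtb_flux_vanishes_at_transporter_equilibrium(self):
        cond = make_condition(nhx_ext=0.01)
        phi = ACTIVE.phi()
        nh4_ext, _ = speciate(0.01, 7.0)
        r_int = 10 ** (7.6 - 9.25)
        nhx_eq = phi * nh4_ext * (1 + r_int)  # internal total giving nh4 = phi*nh4_ext
        state = {"nhx_int": nhx_eq, "gln": 1.0, "glu": 40.0}
        fl = fluxes(state, glnk_knockout(PARAMS), cond)
        assert fl.v_amtb == pytest.approx(0.0, abs=1e-9)

    def test_diffusion_vanishes_when_nh3_equilibrated(self):
        cond = make_condition(nhx_ext=1.0)
        _, nh3_ext = speciate(1.0, 7.0)
        r_int = 10 ** (7.6 - 9.25)
        nhx_int = nh3_ext * (1 + r_int) / r_int
        fl = fluxes({"nhx_int": nhx_int, "gln": 1.0, "glu": 40.0}, PARAMS, cond)
        assert fl.v_diff == pytest.approx(0.0, abs=1e-12)

    def test_term_by_term_arithmetic_oracle(self):
        # every rate recomputed step by step with independent arithmetic
        cond = make_condition(nhx_ext=1.0)
        state = {"nhx_int": 0.1, "gln": 2.0, "glu": 60.0}
        p = PARAMS
        r_int = 10 ** (7.6 - 9.25)
        r_ext = 10 ** (7.0 - 9.25)
        nh4_i = 0.1 / (1 + r_int)
        nh3_i = 0.1 - nh4_i
        nh4_e = 1.0 / (1 + r_ext)
        nh3_e = 1.0 - nh4_e
        phi = math.exp(-96485.0 * -0.150 / (8.314 * 310.0))
        theta = (nh4_i / 0.02) ** 2 / (1 + (nh4_i / 0.02) ** 2)
        v_amtb = 100.0 * (1 - theta) * nh4_e / (0.01 + nh4_e) * (1 - nh4_i / (phi * nh4_e))
        v_diff = 50.0 * (nh3_e - nh3_i)
        v_gs = 40.0 * nh4_i / (0.1 + nh4_i)
        v_use = 10.0 * 2.0
        v_bio = 0.4 * (2.0 / (0.5 + 2.0)) * 60.0
        d = toy_rhs(state, p, cond)
        assert d["nhx_int"] == pytest.approx(v_amtb + v_diff - v_gs, rel=1e-12)
        assert d["gln"] == pytest.approx(v_gs - v_use, rel=1e-12)
        assert d["glu"] == pytest.approx(v_use - v_bio, rel=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(DomainError):
            toy_rhs({"nhx_int": -0.1, "gln": 1.0, "glu": 1.0}, PARAMS, make_condition())

    def test_passive_flux_vanishes_without_nh3_gradient(self):
        cond = make_condition(physics=PASSIVE, nhx_ext=1.0)
        _, nh3_ext = speciate(1.0, 7.0)
        r_int = 10 ** (7.6 - 9.25)
        nhx_int = nh3_ext * (1 + r_int) / r_int
        fl = fluxes({"nhx_int": nhx_int, "gln": 1.0, "glu": 40.0},
                    glnk_knockout(PARAMS), cond)
        assert fl.v_amtb == pytest.approx(0.0, abs=1e-12)
        assert fl.v_diff == pytest.approx(0.0, abs=1e-12)


class TestSimulate:
    def test_near_zero_rates_give_constant_trajectory(self):
        tiny = ToyNetworkParams(
            vmax_amtb=1e-12, km_amtb=0.01, p_diff=1e-12, vmax_gs=1e-12,
            km_gs=0.1, k_glnk=0.02, n_glnk=2.0, mu_max=1e-12, k_growth=0.5,
            k_dil=1e-12,
        )
        traj = simulate(tiny, make_condition(), t_end=30.0, times=[0, 10, 30])
        for var in ("nhx_int", "gln", "glu"):
            vals = traj.data[var].to_numpy()
            np.testing.assert_allclose(vals, vals[0], rtol=1e-8, atol=1e-9)

    def test_mass_balance_along_trajectory(self):
        # d(nhx_int)/dt must equal v_amtb + v_diff - v_gs numerically
        times = np.linspace(0, 5, 201)
        traj = simulate(PARAMS, make_condition(nhx_ext=10.0), t_end=5.0, times=times)
        t = traj.data["time"].to_numpy()
        nhx = traj.data["nhx_int"].to_numpy()
        rate = (traj.data["v_amtb"] + traj.data["v_diff"] - traj.data["v_gs"]).to_numpy()
        deriv = np.gradient(nhx, t)
        mid = slice(5, -5)
        scale = np.max(np.abs(rate)) + 1e-12
        assert np.max(np.abs(deriv[mid] - rate[mid])) / scale < 0.02

    def test_tolerance_convergence_of_endpoints(self):
        cond = make_condition(nhx_ext=10.0)
        a = simulate(PARAMS, cond, 30.0, rtol=1e-7, atol=1e-10)
        b = simulate(PARAMS, cond, 30.0, rtol=5e-8, atol=5e-11)
        ya = a.data.iloc[-1][["nhx_int", "gln", "glu"]].to_numpy(float)
        yb = b.data.iloc[-1][["nhx_int", "gln", "glu"]].to_numpy(float)
        assert np.max(np.abs(ya - yb) / np.abs(yb)) < 1e-3

    def test_step_input_drives_uptake_after_the_step(self):
        cond = Condition(
            condition_id="step", physics=ACTIVE,
            nhx_ext=((0.0, 0.001), (5.0, 10.0)),
            initial_state={"nhx_int": 0.001, "gln": 0.1, "glu": 10.0},
        )
        traj = simulate(PARAMS, cond, t_end=10.0, times=[4.9, 6.0, 10.0])
        before = traj.at(4.9, "nhx_int")
        after = traj.at(10.0, "nhx_int")
        assert after > 2 * before

    def test_rejects_nonpositive_horizon(self):
        with pytest.raises(DomainError):
            simulate(PARAMS, make_condition(), t_end=0.0)


class TestSteadyState:
    def test_transporter_equilibrium_without_assimilation(self):
        # assimilation and GlnK off, active mode: NH4 ratio approaches phi
        p = replace(PARAMS, vmax_gs=1e-10, p_diff=1e-10)
        cond = make_condition(nhx_ext=0.001, knockout=True)
        state, _ = steady_state(p, cond)
        nh4_int, _ = speciate(state["nhx_int"], 7.6)
        nh4_ext, _ = speciate(0.001, 7.0)
        assert nh4_int / nh4_ext == pytest.approx(ACTIVE.phi(), rel=1e-4)

    def test_passive_equal_ph_equilibrates_nh3(self):
        p = replace(PARAMS, vmax_gs=1e-10)
        phys = TransportPhysics(mode="passive", ph_ext=7.6, ph_int=7.6)
        state, _ = steady_state(p, make_condition(physics=phys, nhx_ext=1.0,
                                                  knockout=True))
        _, nh3_int = speciate(state["nhx_int"], 7.6)
        _, nh3_ext = speciate(1.0, 7.6)
        assert nh3_int == pytest.approx(nh3_ext, rel=1e-6)

    def test_agrees_with_long_time_integration(self):
        cond = make_condition(nhx_ext=1.0)
        state, _ = steady_state(PARAMS, cond)
        traj = simulate(PARAMS, cond, t_end=3000.0, rtol=1e-10, atol=1e-13)
        end = traj.data.iloc[-1]
        for var in ("nhx_int", "gln", "glu"):
            assert state[var] == pytest.approx(float(end[var]), rel=1e-6)

    def test_flux_balance_at_steady_state(self):
        state, fl = steady_state(PARAMS, make_condition(nhx_ext=1.0))
        obs = observables(state, PARAMS, make_condition(nhx_ext=1.0))
        assert fl.v_net == pytest.approx(fl.v_amtb + fl.v_diff, rel=1e-12)
        assert fl.v_net == pytest.approx(obs["v_gs"], rel=1e-6)

    def test_active_accumulation_stays_below_equilibrium_ceiling(self):
        # with assimilation running there must be net inward drive
        cond = make_condition(nhx_ext=0.05)
        state, _ = steady_state(PARAMS, cond)
        nh4_int, _ = speciate(state["nhx_int"], 7.6)
        nh4_ext, _ = speciate(0.05, 7.0)
        assert nh4_int < ACTIVE.phi() * nh4_ext


class TestFutileCycle:
    @pytest.mark.parametrize(
        "back,h_nh3,h_atp,expected",
        [(0.0, 1, 3, 0.0), (1300.0, 1, 3, 433.3), (300.0, 1, 3, 100.0)],
    )
    def test_atp_equivalent_arithmetic(self, back, h_nh3, h_atp, expected):
        assert futile_cycle_atp_equivalent(back, h_nh3, h_atp) == pytest.approx(
            expected, abs=0.05)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            futile_cycle_atp_equivalent(-1.0)
        with pytest.raises(DomainError):
            futile_cycle_atp_equivalent(1.0, h_per_atp=0.0)

    def test_futile_cycle_emerges_structurally(self):
        # accumulation above the NH3 ratio forces outward diffusion while
        # the transporter still pumps inward
        state, fl = steady_state(PARAMS, make_condition(nhx_ext=1.0, knockout=True))
        assert fl.v_amtb > 0.0
        assert fl.v_diff < 0.0


class TestGlnkKnockout:
    def test_knockout_unblocks_transport_at_high_ammonium(self):
        wt_state, wt_flux = steady_state(PARAMS, make_condition(nhx_ext=1.0))
        ko_state, ko_flux = steady_state(PARAMS, make_condition(nhx_ext=1.0,
                                                                knockout=True))
        # GlnK throttles AmtB in the wild type; removing it releases the flux
        assert ko_flux.v_amtb > 3 * max(wt_flux.v_amtb, 1e-12)
        assert -ko_flux.v_diff > 10 * max(-wt_flux.v_diff, 1e-12)

    def test_original_parameters_unmodified(self):
        before = PARAMS.as_dict()
        glnk_knockout(PARAMS)
        assert PARAMS.as_dict() == before

    def test_idempotent_on_uninhibited_parameters(self):
        ko = glnk_knockout(PARAMS)
        state = {"nhx_int": 0.5, "gln": 1.0, "glu": 40.0}
        cond = make_condition(nhx_ext=1.0)
        assert fluxes(state, glnk_knockout(ko), cond) == fluxes(state, ko, cond)

    def test_back_diffusion_never_decreases_on_a_grid(self):
        for nhx_ext in (0.05, 0.2, 0.5, 1.0, 2.0):
            _, wt = steady_state(PARAMS, make_condition(nhx_ext=nhx_ext))
            _, ko = steady_state(PARAMS, make_condition(nhx_ext=nhx_ext,
                                                        knockout=True))
            assert max(0.0, -ko.v_diff) >= max(0.0, -wt.v_diff) - 1e-9
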