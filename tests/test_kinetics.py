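"""Membrane flux components: GHK current, Borg-Graham gating, Hill pumps,
leak calibration and the action-potential train."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from azsim import kinetics as K
from azsim.kinetics import (
    APTrainSpec,
    ChannelParams,
    GatingState,
    PhysicalConstants,
    PumpParams,
    ap_voltage,
    calibrate_leak,
    gating_curves,
    ghk_flux,
    init_gating,
    ncx_flux,
    nernst_potential,
    pmca_flux,
    step_gating,
    total_membrane_flux,
    vgcc_current,
)

CONSTS = PhysicalConstants()
CHANNEL = ChannelParams(rho_vgcc=2297.1)
PUMPS = PumpParams()


class TestGHK:
    def test_nernst_potential_value(self):
        # (RT/2F) ln(1.5 mM / 50 nM) with the tabulated constants
        expected = 1e3 * CONSTS.R * CONSTS.T / (2 * CONSTS.F) * math.log(3.0e4)
        assert nernst_potential(0.05, 1500.0) == pytest.approx(expected)
        assert nernst_potential(0.05, 1500.0) == pytest.approx(133.3, abs=0.1)

    def test_zero_at_nernst(self):
        v_rev = nernst_potential(0.05, 1500.0)
        assert abs(ghk_flux(v_rev, 0.05, 1500.0, CHANNEL)) < 1e-25

    def test_low_voltage_limit(self):
        expected = CHANNEL.p_x * CONSTS.z * CONSTS.F * (0.05 - 1500.0) * 1e-3
        assert ghk_flux(0.0, 0.05, 1500.0, CHANNEL) == pytest.approx(expected)
        # continuity of the series branch against the full expression
        assert ghk_flux(1e-7, 0.05, 1500.0, CHANNEL) == pytest.approx(
            ghk_flux(1e-2, 0.05, 1500.0, CHANNEL), rel=1e-3)

    @given(st.floats(-150.0, 250.0), st.floats(-150.0, 250.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_voltage(self, v1, v2):
        f1, f2 = (ghk_flux(v, 0.05, 1500.0, CHANNEL) for v in (v1, v2))
        if v1 < v2:
            assert f1 <= f2 + 1e-30
        elif v1 > v2:
            assert f1 >= f2 - 1e-30

    def test_inward_current_negative_below_reversal(self):
        assert ghk_flux(-70.0, 0.05, 1500.0, CHANNEL) < 0


class TestGating:
    def test_midpoint_and_saturation(self):
        gate = CHANNEL.gates[0]
        x_half, _ = gating_curves(gate.v_half, gate)
        assert x_half == pytest.approx(0.5)
        x_high, _ = gating_curves(300.0, gate)
        assert x_high > 0.999

    def test_tau_floor(self):
        for gate in CHANNEL.gates:
            for v in (-120.0, gate.v_half, 80.0):
                _, tau = gating_curves(v, gate)
                assert tau >= gate.tau_min

    def test_step_identity_and_relaxation(self):
        s0 = init_gating(-70.0, CHANNEL)
        assert np.allclose(step_gating(s0, -70.0, 0.0, CHANNEL).x, s0.x)
        far = step_gating(s0, 10.0, 10.0, CHANNEL)
        x_inf = np.array([gating_curves(10.0, g)[0] for g in CHANNEL.gates])
        assert np.allclose(far.x, x_inf, atol=1e-12)

    def test_one_tau_closed_form(self):
        gate = CHANNEL.gates[0]
        x_inf, tau = gating_curves(0.0, gate)
        state = GatingState(x=np.array([0.0, 1.0]))
        out = step_gating(state, 0.0, tau, CHANNEL)
        # x0 = 0 relaxing one time constant toward x_inf
        assert out.x[0] == pytest.approx(x_inf * (1 - math.exp(-1)), rel=1e-12)

    def test_exponential_update_matches_ode_oracle(self):
        """Piecewise-constant voltage: the exact exponential update must agree
        with a high-accuracy ODE integration to <= 1e-8 relative error."""
        voltages = [-70.0, 20.0, -30.0, -70.0]
        dts = [5e-4, 3e-4, 2e-4, 1e-3]
        state = init_gating(-70.0, CHANNEL)
        x_exact = state.x.copy()
        for v, dt in zip(voltages, dts):
            state = step_gating(state, v, dt, CHANNEL)
            for i, g in enumerate(CHANNEL.gates):
                x_inf, tau = gating_curves(v, g)
                sol = solve_ivp(lambda t, x: (x_inf - x) / tau, (0, dt),
                                [x_exact[i]], rtol=1e-12, atol=1e-14)
                x_exact[i] = sol.y[0, -1]
        assert np.allclose(state.x, x_exact, rtol=1e-8)


class TestVGCC:
    def test_all_gates_open_equals_ghk(self):
        state = GatingState(x=np.ones(len(CHANNEL.gates)))
        assert vgcc_current(-20.0, state, 0.05, 1500.0, CHANNEL) == pytest.approx(
            ghk_flux(-20.0, 0.05, 1500.0, CHANNEL))

    def test_closed_gate_blocks(self):
        state = GatingState(x=np.array([0.0, 1.0]))
        assert vgcc_current(-20.0, state, 0.05, 1500.0, CHANNEL) == 0.0

    def test_power_law(self):
        state = GatingState(x=np.array([0.5, 1.0]))  # m^2 h -> 0.25
        assert vgcc_current(-20.0, state, 0.05, 1500.0, CHANNEL) == pytest.approx(
            0.25 * ghk_flux(-20.0, 0.05, 1500.0, CHANNEL))


class TestPumps:
    def test_half_saturation(self):
        assert pmca_flux(0.06, PUMPS) == pytest.approx(PUMPS.I_p / 2)
        assert ncx_flux(1.8, PUMPS) == pytest.approx(PUMPS.I_x / 2)

    def test_zero_and_saturation(self):
        assert pmca_flux(0.0, PUMPS) == 0.0
        assert ncx_flux(0.0, PUMPS) == 0.0
        assert ncx_flux(1e9, PUMPS) == pytest.approx(PUMPS.I_x, rel=1e-6)

    def test_hill_evaluation_at_double_half_saturation(self):
        # Ca = 120 nM with H_p = 60 nM, n_p = 2 -> 0.8 I_p
        assert pmca_flux(0.12, PUMPS) == pytest.approx(0.8 * PUMPS.I_p)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, c1, c2):
        lo, hi = sorted((c1, c2))
        assert pmca_flux(lo, PUMPS) <= pmca_flux(hi, PUMPS) <= PUMPS.I_p
        assert ncx_flux(lo, PUMPS) <= ncx_flux(hi, PUMPS) <= PUMPS.I_x


class TestLeakCalibration:
    def test_rest_flux_zero_after_calibration(self):
        pumps = calibrate_leak(CHANNEL, PUMPS, 0.05, 1500.0, -70.0)
        state = init_gating(-70.0, CHANNEL)
        rest = total_membrane_flux(-70.0, state, 0.05, CHANNEL, pumps, 1500.0)
        assert abs(rest) < 1e-10

    def test_nothing_to_balance(self):
        quiet = PUMPS.with_(rho_pmca=0.0, rho_ncx=0.0)
        no_influx = CHANNEL.with_(rho_vgcc=0.0)
        pumps = calibrate_leak(no_influx, quiet, 0.05, 1500.0, -70.0)
        assert pumps.leak_density == 0.0

    def test_leak_matches_bruteforce_term_sum(self):
        """Independent summation of the flux terms at rest."""
        pumps = calibrate_leak(CHANNEL, PUMPS, 0.05, 1500.0, -70.0)
        state = init_gating(-70.0, CHANNEL)
        vgcc = CHANNEL.rho_vgcc * (-vgcc_current(-70.0, state, 0.05, 1500.0, CHANNEL)
                                   / (CONSTS.z * CONSTS.F)) * K.MOL_TO_UM_UM3
        pump_out = (PUMPS.rho_pmca * pmca_flux(0.05, PUMPS)
                    + PUMPS.rho_ncx * ncx_flux(0.05, PUMPS)) * K.MOL_TO_UM_UM3
        assert pumps.leak_density == pytest.approx(pump_out - vgcc, rel=1e-12)

    def test_unit_conversion_one_pump(self):
        # a saturated PMCA pump extrudes I_p = 8e-24 mol/s = 8e-3 uM um^3/s
        assert pmca_flux(1e6, PUMPS) * K.MOL_TO_UM_UM3 == pytest.approx(8.0e-3, rel=1e-4)

    def test_flux_linear_in_channel_density(self):
        state = init_gating(20.0, CHANNEL)
        quiet = PUMPS.with_(rho_pmca=0.0, rho_ncx=0.0, leak_density=0.0)
        f1 = total_membrane_flux(20.0, state, 0.05, CHANNEL, quiet, 1500.0)
        f2 = total_membrane_flux(20.0, state, 0.05,
                                 CHANNEL.with_(rho_vgcc=2 * CHANNEL.rho_vgcc), quiet, 1500.0)
        assert f2 == pytest.approx(2 * f1)

    def test_well_mixed_surrogate_holds_resting_calcium(self):
        """Zero-dimensional surrogate: with the calibrated leak, a well-mixed
        compartment stays at 50 nM without stimulation."""
        pumps = calibrate_leak(CHANNEL, PUMPS, 0.05, 1500.0, -70.0)
        area, volume = 0.0028, 0.027  # channel area and compartment volume, um^2 / um^3
        ca = 0.05
        state = init_gating(-70.0, CHANNEL)
        for _ in range(2000):
            flux = total_membrane_flux(-70.0, state, ca, CHANNEL, pumps, 1500.0)
            ca += 1e-5 * flux * area / volume
        assert ca == pytest.approx(0.05, rel=1e-9)


class TestAPTrain:
    def test_rest_between_spikes(self):
        train = APTrainSpec(frequency=40.0)
        assert ap_voltage(0.0, train) == pytest.approx(train.v_rest)
        assert ap_voltage(0.024, train) == pytest.approx(train.v_rest, abs=0.05)

    def test_periodicity_and_onsets(self):
        train = APTrainSpec(frequency=40.0)
        t_dense = np.linspace(0.0, train.period, 2001)
        v0 = ap_voltage(t_dense, train)
        v1 = ap_voltage(t_dense + train.period, train)
        assert np.allclose(v0, v1, atol=1e-9)
        assert np.allclose(train.spike_onsets(0.1), np.arange(4) * 0.025)

    def test_peak_amplitude(self):
        train = APTrainSpec(frequency=40.0)
        t_dense = np.linspace(0.0, train.period, 200001)
        assert ap_voltage(t_dense, train).max() == pytest.approx(train.v_peak, abs=0.01)

    def test_sampled_waveform_overrides_template(self):
        wf = ((0.0, -70.0), (0.001, -70.0), (0.0015, 10.0), (0.002, -70.0))
        train = APTrainSpec(frequency=40.0, waveform=wf)
        assert ap_voltage(0.0015, train) == pytest.approx(10.0)
        assert ap_voltage(0.00125, train) == pytest.approx(-30.0)  # linear interp
        assert ap_voltage(0.010, train) == pytest.approx(-70.0)    # outside samples
        assert ap_voltage(0.025 + 0.0015, train) == pytest.approx(10.0)  # periodic

    def test_bad_sampled_waveform_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            APTrainSpec(frequency=40.0, waveform=((0.0, -70.0), (0.0, 0.0)))
        with pytest.raises(ValueError, match="support"):
            APTrainSpec(frequency=40.0, waveform=((0.0, -70.0), (0.03, 0.0)))

    def test_matched_evaluation_time_20hz_100hz(self):
        # the second 20 Hz spike and the fifth later 100 Hz spike share t = 50 ms
        t20 = APTrainSpec(frequency=20.0).spike_onsets(0.06)[1]
        t100 = APTrainSpec(frequency=100.0).spike_onsets(0.06)[5]
        assert t20 == pytest.approx(t100) == pytest.approx(0.05)
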