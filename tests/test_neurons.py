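"""AdEx neuron dynamics: fixed points, reset bookkeeping, rheobase,
electrophysiological measurements, and integration accuracy."""

import numpy as np
import pytest

from dbcnet import params as P
from dbcnet.errors import MeasurementError
from dbcnet.neurons import (NeuronParams, NeuronState, adex_step,
                            detect_and_reset, fI_curve,
                            measure_input_resistance)


def _run(params, i_ext, duration, dt=0.1, v0=None):
    state = NeuronState.resting(params, 1)
    if v0 is not None:
        state.v[:] = v0
    spike_times, trace = [], []
    for k in range(int(round(duration / dt))):
        state = adex_step(state, params, 0.0, i_ext, dt)
        state, spiked = detect_and_reset(state, params)
        if spiked[0]:
            spike_times.append((k + 1) * dt)
        trace.append(state.v[0])
    return state, np.array(spike_times), np.array(trace)


class TestMembraneEquation:
    def test_rest_is_a_fixed_point(self, dbc):
        state = NeuronState.resting(dbc, 1)
        for _ in range(1000):
            state = adex_step(state, dbc, 0.0, 0.0, 0.1)
        # exponential-term leak at rest is ~1e-14 of a millivolt for the DBC
        assert state.v[0] == pytest.approx(dbc.e_l, abs=1e-9)

    def test_subthreshold_relaxation_is_monotone(self, dbc):
        _, spikes, trace = _run(dbc, 0.0, 200.0, v0=-66.0)
        assert len(spikes) == 0
        diffs = np.diff(np.concatenate([[-66.0], trace]))
        assert np.all(diffs <= 1e-12)
        assert trace[-1] == pytest.approx(dbc.e_l, abs=0.05)

    def test_membrane_time_constant_in_reported_window(self, dbc):
        assert dbc.tau_m == pytest.approx(9.87, abs=0.01)
        assert 17.1 - 7.7 < dbc.tau_m < 17.1 + 7.7

    def test_non_finite_state_rejected(self, dbc):
        state = NeuronState.resting(dbc, 1)
        state.v[0] = np.nan
        with pytest.raises(ValueError):
            adex_step(state, dbc, 0.0, 0.0, 0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(c_m=-1, g_l=1, e_l=-70, v_t=-50, delta_t=1,
                         b=0, tau_w=100, v_r=-60, tau_ref=2)
        with pytest.raises(ValueError):
            NeuronParams(c_m=100, g_l=1, e_l=-70, v_t=-50, delta_t=1,
                         b=0, tau_w=100, v_r=-40, tau_ref=2)  # v_r > v_t


class TestSpikingAndReset:
    def test_reset_applies_table_values(self, dbc):
        state = NeuronState(v=np.array([dbc.v_cut + 1.0]),
                            i_w=np.zeros(1), ref_ms=np.zeros(1))
        state, spiked = detect_and_reset(state, dbc)
        assert spiked[0]
        assert state.v[0] == -60.0
        assert state.i_w[0] == 3.0
        assert state.ref_ms[0] == dbc.tau_ref

    def test_below_cutoff_unchanged(self, dbc):
        state = NeuronState(v=np.array([dbc.v_t - 1.0]),
                            i_w=np.array([1.5]), ref_ms=np.zeros(1))
        out, spiked = detect_and_reset(state, dbc)
        assert not spiked[0]
        assert out.v[0] == state.v[0] and out.i_w[0] == state.i_w[0]

    def test_adaptation_decay_between_spikes_closed_form(self, dbc):
        # spike, decay 10 ms, spike again: I_w = b e^(-10/tau_w) + b
        state = NeuronState(v=np.array([dbc.v_cut + 1.0]),
                            i_w=np.zeros(1), ref_ms=np.zeros(1))
        state, _ = detect_and_reset(state, dbc)
        for _ in range(100):
            state = adex_step(state, dbc, 0.0, 0.0, 0.1)
        state.v[0] = dbc.v_cut + 1.0
        state, _ = detect_and_reset(state, dbc)
        expected = 3.0 * np.exp(-10.0 / 200.0) + 3.0
        assert state.i_w[0] == pytest.approx(expected, rel=1e-12)

    def test_regular_spiking_with_mild_rate_decline(self, dbc):
        _, spikes, _ = _run(dbc, 90.0, 1000.0)
        assert len(spikes) > 30
        isis = np.diff(spikes)
        # adaptation (b = 3 pA) slows firing over the step without silencing
        assert isis[-1] > isis[0]
        assert isis[-1] < 3.0 * isis[0]
        # firing is sustained: spikes occur throughout the final quarter
        assert spikes[-1] > 900.0

    def test_no_spike_below_rheobase(self, dbc):
        assert dbc.rheobase == pytest.approx(47.12, abs=0.01)
        _, spikes, _ = _run(dbc, 40.0, 2000.0)
        assert len(spikes) == 0

    def test_refractory_period_enforced(self, dbc):
        _, spikes, _ = _run(dbc, 300.0, 500.0)
        assert len(spikes) > 5
        assert np.all(np.diff(spikes) >= dbc.tau_ref - 1e-9)


class TestMeasurements:
    def test_dbc_input_resistance_matches_reported(self, dbc):
        r = measure_input_resistance(dbc, i_step=-5.0)
        assert r == pytest.approx(660.0, rel=0.05)

    def test_input_resistance_is_one_over_leak(self):
        prm = NeuronParams(c_m=100, g_l=10.0, e_l=-70, v_t=-50, delta_t=0.1,
                           b=0, tau_w=100, v_r=-60, tau_ref=2)
        assert measure_input_resistance(prm, i_step=-10.0) == pytest.approx(
            100.0, rel=0.01)

    def test_subthreshold_linearity(self, dbc):
        r1 = measure_input_resistance(dbc, i_step=-1.0)
        r5 = measure_input_resistance(dbc, i_step=-5.0)
        assert r1 == pytest.approx(r5, rel=0.02)

    def test_depolarizing_step_invalidates_measurement(self, dbc):
        with pytest.raises(MeasurementError):
            measure_input_resistance(dbc, i_step=200.0)

    def test_fi_curve_monotone_and_zero_below_rheobase(self, dbc):
        currents = np.linspace(10.0, 150.0, 10)
        rates = fI_curve(dbc, currents, duration=1000.0)
        assert np.all(np.diff(rates) >= 0)
        assert np.all(rates[currents < dbc.rheobase] == 0)

    def test_strong_stimulation_rate_in_reported_band(self, dbc):
        rate = fI_curve(dbc, [P.DBC_STRONG_STEP_PA], duration=2000.0)[0]
        assert 43 - 13 <= rate <= 43 + 13

    def test_empty_current_list_rejected(self, dbc):
        with pytest.raises(ValueError):
            fI_curve(dbc, [], duration=1000.0)


class TestIntegrationAccuracy:
    def test_subthreshold_trajectory_converges_with_dt(self, dbc):
        _, _, coarse = _run(dbc, 30.0, 200.0, dt=0.1)
        _, _, fine = _run(dbc, 30.0, 200.0, dt=0.01)
        v_coarse = coarse[-1] - dbc.e_l
        v_fine = fine[-1] - dbc.e_l
        assert v_coarse == pytest.approx(v_fine, rel=0.01)

    def test_spike_count_converges_with_dt(self, dbc):
        _, s_coarse, _ = _run(dbc, 90.0, 1000.0, dt=0.1)
        _, s_fine, _ = _run(dbc, 90.0, 1000.0, dt=0.01)
        assert abs(len(s_coarse) - len(s_fine)) <= 1
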