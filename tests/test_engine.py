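"""Integration loop: silence, determinism, conduction delays, consistency
with the standalone neuron stepper, and dt-refinement stability."""

import numpy as np
import pytest

from dbcnet import params as P
from dbcnet.config import from_dict
from dbcnet.engine import EngineConfig, run
from dbcnet.errors import ConfigurationError
from dbcnet.network import Network, NetworkSpec, Projection, build
from dbcnet.neurons import NeuronState, adex_step, detect_and_reset
from dbcnet.stimulation import NoiseSpec, Protocol, StimulusSpec
from dbcnet.workflows import run_default_trial


def tiny_network(n=2, projections=None):
    pops = {f"pyr_mc{i}": np.array([i]) for i in range(n)}
    return Network(
        spec=NetworkSpec(), n_neurons=n,
        cell_class=np.array(["pyr"] * n),
        populations=pops, projections=projections or [],
        neuron_params=dict(P.NEURON_DEFAULTS),
    )


SILENT = Protocol(stimuli=(), noise=NoiseSpec(rate=0.0))


class TestBasics:
    def test_silent_network_stays_at_rest(self):
        net = tiny_network()
        cfg = EngineConfig(t_end=300.0, snapshot_times=(300.0,),
                           record_current_populations=(),
                           record_voltage_ids=(0, 1), tonic_current=())
        rec = run(net, SILENT, cfg)
        assert len(rec.spikes) == 0
        # rest sits within the tiny upstroke-term offset of E_L
        v = rec.voltages.to_numpy()
        assert np.allclose(v, P.PYRAMIDAL.e_l, atol=0.05)

    def test_zero_weight_default_network_is_silent(self):
        zeros = {k: {"weight": 0.0, "g_gain": 0.0}
                 for k in P.PROJECTION_DEFAULTS}
        net = build(NetworkSpec(rng_seed=0), projection_params=zeros)
        cfg = EngineConfig(t_end=500.0, snapshot_times=(500.0,),
                           record_current_populations=(), tonic_current=())
        rec = run(net, SILENT, cfg)
        assert len(rec.spikes) == 0

    def test_identical_seeds_give_identical_recordings(self):
        cfg = from_dict({"engine": {"t_end": 1500.0,
                                    "snapshot_times": [1000.0, 1500.0]}})
        a = run_default_trial(7, cfg)
        b = run_default_trial(7, cfg)
        assert a.spikes.equals(b.spikes)
        assert a.weight_snapshots.equals(b.weight_snapshots)
        np.testing.assert_array_equal(a.currents["pyr_mc0"].i_gaba,
                                      b.currents["pyr_mc0"].i_gaba)

    def test_different_seeds_differ(self):
        cfg = from_dict({"engine": {"t_end": 1500.0,
                                    "snapshot_times": [1500.0]}})
        a = run_default_trial(7, cfg)
        b = run_default_trial(8, cfg)
        assert not a.spikes.equals(b.spikes)


class TestDelays:
    @pytest.mark.parametrize("delay", [1.5, 4.5])
    def test_spike_affects_target_no_earlier_than_delay(self, delay):
        proj = Projection(
            name="pyr_mc0->pyr_mc1", kind="static",
            pre=np.array([0]), post=np.array([1]), receptor="ampa",
            delay=delay, plastic=False, depressing=False,
            weight=5.0, g_gain=1.0, u=0.25, tau_rec=500.0)
        net = tiny_network(projections=[proj])
        stim = StimulusSpec(label="kick", rate=5000.0, window=(100.0, 102.0),
                            targets=(("pyr", 0),), weight=20.0)
        cfg = EngineConfig(t_end=200.0, snapshot_times=(200.0,),
                           record_current_populations=("pyr_mc1",),
                           tonic_current=())
        rec = run(net, Protocol(stimuli=(stim,), noise=NoiseSpec(rate=0.0)), cfg)
        pre_spikes = rec.spikes[rec.spikes.neuron == 0].time.to_numpy()
        assert len(pre_spikes) > 0
        i_ampa = rec.currents["pyr_mc1"].i_ampa[:, 0]
        onset = (np.flatnonzero(i_ampa > 1e-9)[0] + 1) * cfg.dt
        assert onset >= pre_spikes[0] + delay - 1e-9
        assert onset <= pre_spikes[0] + delay + 1.0   # arrives promptly too


class TestNeuronConsistency:
    def test_engine_matches_standalone_adex_stepper(self):
        """A one-neuron network under constant current reproduces the
        standalone AdEx trajectory bit-for-bit."""
        net = tiny_network(n=1)
        cfg = EngineConfig(t_end=500.0, snapshot_times=(500.0,),
                           record_current_populations=(),
                           record_voltage_ids=(0,),
                           tonic_current=(("pyr", 260.0),))
        rec = run(net, SILENT, cfg)
        state = NeuronState.resting(P.PYRAMIDAL, 1)
        expected, times = [], []
        for k in range(5000):
            state = adex_step(state, P.PYRAMIDAL, 0.0, 260.0, 0.1)
            state, spiked = detect_and_reset(state, P.PYRAMIDAL)
            expected.append(state.v[0])
            if spiked[0]:
                times.append((k + 1) * 0.1)
        # voltage traces are stored as float32; spike times are exact
        np.testing.assert_allclose(rec.voltages["0"].to_numpy(), expected,
                                   rtol=1e-5, atol=1e-3)
        np.testing.assert_allclose(
            rec.spikes.time.to_numpy(), times, rtol=1e-12)
        assert len(times) > 3


class TestSignsAndStability:
    def test_recorded_gaba_current_is_hyperpolarizing(self):
        cfg = from_dict({"engine": {"t_end": 1200.0,
                                    "snapshot_times": [1200.0]}})
        rec = run_default_trial(0, cfg)
        assert np.all(rec.currents["pyr_mc0"].i_gaba <= 1e-9)

    def test_halving_dt_changes_totals_mildly(self):
        base = {"engine": {"t_end": 2000.0, "snapshot_times": [1000.0],
                           "record_current_populations": []}}
        rec1 = run_default_trial(0, from_dict(base))
        base["engine"]["dt"] = 0.05
        rec2 = run_default_trial(0, from_dict(base))
        n1, n2 = len(rec1.spikes), len(rec2.spikes)
        assert abs(n1 - n2) / n1 < 0.05


class TestConfigErrors:
    def test_snapshot_beyond_run_rejected(self):
        with pytest.raises(ConfigurationError):
            EngineConfig(t_end=100.0, snapshot_times=(200.0,))

    def test_delay_not_multiple_of_dt_rejected(self):
        net = build(NetworkSpec(rng_seed=0))
        cfg = EngineConfig(dt=0.4, t_end=10.0, snapshot_times=(10.0,),
                           record_current_populations=())
        with pytest.raises(ConfigurationError, match="multiple"):
            run(net, SILENT, cfg)

    def test_unknown_stimulus_target_rejected(self):
        net = tiny_network()
        stim = StimulusSpec(label="x", rate=10.0, window=(0.0, 10.0),
                            targets=(("dbc", 5),), weight=1.0)
        cfg = EngineConfig(t_end=20.0, snapshot_times=(20.0,),
                           record_current_populations=())
        with pytest.raises(ConfigurationError, match="target"):
            run(net, Protocol(stimuli=(stim,), noise=NoiseSpec(rate=0.0)), cfg)
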