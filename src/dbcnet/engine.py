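"""Clock-driven integration of the full microcircuit.

One step of the loop, in order: (1) decay conductances and recover
depression resources; (2) deliver spikes whose conduction delay elapses at
this step (depression jump plus conductance increment, plastic synapses
using their *current* Bayesian weight at delivery time); (3) advance the
plasticity traces; (4) inject stimulus and noise events; (5) sum synaptic
currents per receptor; (6) advance the membrane equations, detect and reset
spikes, and enqueue them in the delay ring; (7) record.

Delays are realized as a ring buffer of per-step spike vectors, so every
delay must be an integer multiple of dt (the defaults 1.5/4.5 ms are 15 and
45 steps at dt = 0.1 ms).  The BCPNN pre-side traces are driven by the
*delay-shifted* presynaptic spike train (one trace per conduction-delay
class per neuron), matching the view of the synapse, while post-side traces
use emission times.

All randomness flows through named child streams of the configured seed
(one per stimulus, one for the noise), so any source can be varied
independently and identical seeds give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as P
from .errors import ConfigurationError, SimulationError
from .network import Network
from .plasticity import BcpnnParams
from .stimulation import Protocol, generate_spike_train

__all__ = ["EngineConfig", "CurrentRecording", "RecordingSet", "run"]


@dataclass(frozen=True)
class EngineConfig:
    """Integration and recording settings."""

    dt: float = 0.1                     # ms
    t_end: float = P.T_END_DEFAULT      # ms
    seed: int = 0
    record_spikes: bool = True
    snapshot_times: tuple[float, ...] = P.SNAPSHOT_TIMES
    record_current_populations: tuple[str, ...] = ("pyr_mc0",)
    record_voltage_ids: tuple[int, ...] = ()
    tonic_current: tuple[tuple[str, float], ...] = P.TONIC_CURRENT  # pA per class
    beta_gain: float = P.BETA_GAIN
    check_every: int = 2000             # steps between finiteness audits

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ConfigurationError("engine.dt and engine.t_end must be positive")
        for t in self.snapshot_times:
            if not (0 < t <= self.t_end + 1e-9):
                raise ConfigurationError(
                    f"engine.snapshot_times: {t} outside (0, t_end]")


@dataclass
class CurrentRecording:
    """Per-neuron synaptic input currents of one population (pA).

    ``i_gaba`` is the current through network GABA synapses (basket and DBC
    output); by the sign convention it is <= 0 whenever the membrane sits
    above E_GABA.  ``i_ampa`` covers network AMPA synapses plus stimulus
    events.  The zero-mean noise channel is excluded from both.
    """

    population: str
    neuron_ids: np.ndarray
    dt: float
    i_gaba: np.ndarray   # (n_steps, n_neurons) float32
    i_ampa: np.ndarray


@dataclass
class RecordingSet:
    """Everything a run records: spikes, weight snapshots, currents."""

    spikes: pd.DataFrame                     # columns: neuron, time (ms)
    weight_snapshots: pd.DataFrame           # per connection per snapshot
    currents: dict[str, CurrentRecording]
    populations: dict[str, np.ndarray]
    cell_class: np.ndarray
    config: EngineConfig
    voltages: pd.DataFrame | None = None     # optional, per record_voltage_ids

    def spike_times(self, neuron_ids: np.ndarray) -> np.ndarray:
        mask = self.spikes["neuron"].isin(np.asarray(neuron_ids))
        return self.spikes.loc[mask, "time"].to_numpy()

    def to_dir(self, path) -> None:
        """Write the recordings as plain tabular files (spikes, weights,
        per-population mean current traces)."""
        import json
        from pathlib import Path

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / "spikes.csv", index=False)
        self.weight_snapshots.to_csv(out / "weights.csv", index=False)
        for label, rec in self.currents.items():
            df = pd.DataFrame({
                "time": (np.arange(rec.i_gaba.shape[0]) + 1) * rec.dt,
                "i_gaba_mean": rec.i_gaba.mean(axis=1),
                "i_ampa_mean": rec.i_ampa.mean(axis=1),
            })
            df.attrs["n_neurons"] = len(rec.neuron_ids)
            df.to_csv(out / f"currents_{label}.csv", index=False)
        meta = {
            "populations": {k: v.tolist() for k, v in self.populations.items()},
            "cell_class": self.cell_class.tolist(),
            "dt": self.config.dt,
            "t_end": self.config.t_end,
            "current_n_neurons": {k: len(v.neuron_ids)
                                  for k, v in self.currents.items()},
        }
        (out / "meta.json").write_text(json.dumps(meta))


class _ClassArrays:
    """Per-neuron AdEx parameter arrays assembled from the class map."""

    def __init__(self, network: Network):
        n = network.n_neurons
        self.c_m = np.empty(n)
        self.g_l = np.empty(n)
        self.e_l = np.empty(n)
        self.v_t = np.empty(n)
        self.delta_t = np.empty(n)
        self.b = np.empty(n)
        self.tau_w = np.empty(n)
        self.v_r = np.empty(n)
        self.tau_ref = np.empty(n)
        self.v_cut = np.empty(n)
        for cls, prm in network.neuron_params.items():
            m = network.cell_class == cls
            self.c_m[m] = prm.c_m
            self.g_l[m] = prm.g_l
            self.e_l[m] = prm.e_l
            self.v_t[m] = prm.v_t
            self.delta_t[m] = prm.delta_t
            self.b[m] = prm.b
            self.tau_w[m] = prm.tau_w
            self.v_r[m] = prm.v_r
            self.tau_ref[m] = prm.tau_ref
            self.v_cut[m] = prm.v_cut


def _delay_steps(delay: float, dt: float) -> int:
    steps = delay / dt
    if abs(steps - round(steps)) > 1e-6:
        raise ConfigurationError(
            f"delay {delay} ms is not an integer multiple of dt = {dt} ms")
    return int(round(steps))


def run(
    network: Network,
    protocol: Protocol,
    config: EngineConfig,
    bcpnn: BcpnnParams | None = None,
) -> RecordingSet:
    """Simulate the network under the protocol; fully reproducible per seed."""
    bcpnn = bcpnn or P.BCPNN_DEFAULTS
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    n = network.n_neurons
    prm = _ClassArrays(network)

    # ---- synapse bookkeeping -------------------------------------------
    plastic = [p for p in network.projections if p.plastic]
    static = [p for p in network.projections if not p.plastic]

    def concat(projs, attr):
        if not projs:
            return np.empty(0)
        return np.concatenate([np.asarray(getattr(p, attr)) for p in projs])

    pl_pre = concat(plastic, "pre").astype(int)
    pl_post = concat(plastic, "post").astype(int)
    pl_g_gain = np.concatenate(
        [np.full(p.n_connections, p.g_gain) for p in plastic]) if plastic else np.empty(0)
    pl_u = np.concatenate(
        [np.full(p.n_connections, p.u) for p in plastic]) if plastic else np.empty(0)
    pl_tau_rec = np.concatenate(
        [np.full(p.n_connections, p.tau_rec) for p in plastic]) if plastic else np.empty(0)
    pl_dsteps = np.concatenate(
        [np.full(p.n_connections, _delay_steps(p.delay, dt), dtype=int)
         for p in plastic]) if plastic else np.empty(0, int)
    pl_proj = np.concatenate(
        [np.full(p.n_connections, i, dtype=int)
         for i, p in enumerate(plastic)]) if plastic else np.empty(0, int)
    n_plastic = len(pl_pre)

    st_pre = concat(static, "pre").astype(int)
    st_post = concat(static, "post").astype(int)
    st_inc = np.concatenate(
        [np.full(p.n_connections, p.g_gain * p.weight) for p in static]) if static else np.empty(0)
    st_dsteps = np.concatenate(
        [np.full(p.n_connections, _delay_steps(p.delay, dt), dtype=int)
         for p in static]) if static else np.empty(0, int)
    st_gaba = np.concatenate(
        [np.full(p.n_connections, p.receptor == "gaba", dtype=bool)
         for p in static]) if static else np.empty(0, bool)
    st_ampa = ~st_gaba

    # delay classes for the plasticity pre-side traces
    classes = np.unique(pl_dsteps) if n_plastic else np.array([0])
    class_of = {d: i for i, d in enumerate(classes)}
    pl_class = (np.array([class_of[d] for d in pl_dsteps], dtype=int)
                if n_plastic else np.empty(0, int))

    max_delay = int(max(
        [1] + list(pl_dsteps) + list(st_dsteps)))
    ring_len = max_delay + 1
    ring = np.zeros((ring_len, n), dtype=bool)

    # ---- plasticity traces ---------------------------------------------
    eps = bcpnn.eps
    az = dt / bcpnn.tau_z
    ap = bcpnn.kappa * dt / bcpnn.tau_p
    inc_z = 1.0 / (bcpnn.f_max * 1e-3 * bcpnn.tau_z)
    z_post = np.full(n, eps)
    z_pre = np.full((len(classes), n), eps)
    p_post = np.full(n, eps)
    p_pre = np.full((len(classes), n), eps)
    p_ij = np.full(n_plastic, eps * eps)
    x_dep = np.ones(n_plastic)

    # ---- neuron state ---------------------------------------------------
    v = prm.e_l.copy()
    i_w = np.zeros(n)
    ref = np.zeros(n)
    decay_w = np.exp(-dt / prm.tau_w)
    i_tonic = np.zeros(n)
    for cls, amp in config.tonic_current:
        i_tonic[network.cell_class == cls] += amp

    # ---- conductances ---------------------------------------------------
    g_ampa = np.zeros(n)
    g_gaba = np.zeros(n)
    g_ne = np.zeros(n)
    g_ni = np.zeros(n)
    f_a = np.exp(-dt / P.TAU_AMPA)
    f_g = np.exp(-dt / P.TAU_GABA)
    f_rec = np.exp(-dt / pl_tau_rec) if n_plastic else np.empty(0)
    one_minus_u = 1.0 - pl_u

    # ---- external input --------------------------------------------------
    root = np.random.SeedSequence(config.seed)
    stim_seeds, noise_seed = root.spawn(2)
    stim_streams = stim_seeds.spawn(max(len(protocol.stimuli), 1))
    stim_inc = np.zeros((n_steps, n), dtype=np.float32)
    for spec, seq in zip(protocol.stimuli, stim_streams):
        rng = np.random.default_rng(seq)
        for cls, mc in spec.targets:
            label = f"{cls}_mc{mc}"
            if label not in network.populations:
                raise ConfigurationError(
                    f"stimulus {spec.label}: unknown target population {label}")
            for nid in network.populations[label]:
                times = generate_spike_train(spec.rate, spec.window, rng)
                steps = np.minimum((times / dt).astype(int), n_steps - 1)
                np.add.at(stim_inc, (steps, nid), spec.weight)
    noise_rng = np.random.default_rng(noise_seed)
    noise = protocol.noise
    lam = noise.rate * 1e-3 * dt                # expected events per step
    noise_scale = np.ones(n)
    for cls, s in noise.class_scale:
        noise_scale[network.cell_class == cls] = s
    g_exc_amp = noise.g_exc * noise_scale
    g_inh_amp = noise.g_inh_effective * noise_scale

    # ---- recording -------------------------------------------------------
    spike_step_ids: list[np.ndarray] = []
    spike_step_t: list[float] = []
    snapshot_steps = {}
    for t_snap in config.snapshot_times:
        step = int(round(t_snap / dt)) - 1
        if not (0 <= step < n_steps):
            raise ConfigurationError(
                f"engine.snapshot_times: {t_snap} outside the run")
        snapshot_steps.setdefault(step, t_snap)
    snapshots: list[pd.DataFrame] = []

    rec_currents: dict[str, CurrentRecording] = {}
    for label in config.record_current_populations:
        ids = network.population(label)
        rec_currents[label] = CurrentRecording(
            population=label, neuron_ids=ids, dt=dt,
            i_gaba=np.zeros((n_steps, len(ids)), dtype=np.float32),
            i_ampa=np.zeros((n_steps, len(ids)), dtype=np.float32),
        )
    rec_v_ids = np.asarray(config.record_voltage_ids, dtype=int)
    rec_v = (np.zeros((n_steps, len(rec_v_ids)), dtype=np.float32)
             if len(rec_v_ids) else None)

    plastic_names = [p.name for p in plastic]

    def take_snapshot(t_ms: float) -> pd.DataFrame:
        w = np.log(p_ij / (p_pre[pl_class, pl_pre] * p_post[pl_post]))
        return pd.DataFrame({
            "t": t_ms,
            "projection": [plastic_names[i] for i in pl_proj],
            "pre": pl_pre, "post": pl_post, "w": w,
            "p_i": p_pre[pl_class, pl_pre], "p_j": p_post[pl_post],
            "p_ij": p_ij, "beta_j": np.log(p_post[pl_post]),
        })

    # ---- main loop -------------------------------------------------------
    for t in range(n_steps):
        # (1) decay
        g_ampa *= f_a
        g_gaba *= f_g
        g_ne *= f_a
        g_ni *= f_g
        if n_plastic:
            x_dep = 1.0 - (1.0 - x_dep) * f_rec

        # (2) delayed spike delivery
        if len(st_pre):
            delivered = ring[(t - st_dsteps) % ring_len, st_pre]
            if delivered.any():
                hit_a = delivered & st_ampa
                hit_g = delivered & st_gaba
                if hit_a.any():
                    g_ampa += np.bincount(st_post[hit_a],
                                          weights=st_inc[hit_a], minlength=n)
                if hit_g.any():
                    g_gaba += np.bincount(st_post[hit_g],
                                          weights=st_inc[hit_g], minlength=n)
        if n_plastic:
            delivered = ring[(t - pl_dsteps) % ring_len, pl_pre]
            idx = np.flatnonzero(delivered)
            if len(idx):
                pre_i = pl_pre[idx]
                w_now = np.log(
                    p_ij[idx]
                    / (p_pre[pl_class[idx], pre_i] * p_post[pl_post[idx]]))
                inc = (pl_g_gain[idx] * np.maximum(w_now, 0.0)
                       * pl_u[idx] * x_dep[idx])
                g_ampa += np.bincount(pl_post[idx], weights=inc, minlength=n)
                x_dep[idx] *= one_minus_u[idx]

        # (3) plasticity traces (post at emission, pre delay-shifted)
        s_post = ring[(t - 1) % ring_len]
        z_post += az * (eps - z_post)
        z_post[s_post] += inc_z
        for ci, d in enumerate(classes):
            s_pre = ring[(t - d) % ring_len]
            z_pre[ci] += az * (eps - z_pre[ci])
            z_pre[ci][s_pre] += inc_z
        if ap > 0:
            p_post += ap * (z_post - p_post)
            p_pre += ap * (z_pre - p_pre)
            if n_plastic:
                p_ij += ap * (z_pre[pl_class, pl_pre] * z_post[pl_post] - p_ij)

        # (4) external input
        g_ampa += stim_inc[t]
        if noise.rate > 0:
            g_ne += g_exc_amp * noise_rng.poisson(lam, n)
            g_ni += g_inh_amp * noise_rng.poisson(lam, n)

        # (5) synaptic currents (noise kept out of the recorded channels)
        i_ampa_net = -g_ampa * (v - P.E_AMPA)
        i_gaba_net = -g_gaba * (v - P.E_GABA)
        i_noise = -g_ne * (v - P.E_AMPA) - g_ni * (v - P.E_GABA)
        i_syn = i_ampa_net + i_gaba_net + i_noise

        for rec in rec_currents.values():
            rec.i_gaba[t] = i_gaba_net[rec.neuron_ids]
            rec.i_ampa[t] = i_ampa_net[rec.neuron_ids]

        # (6) membrane update, spike detection, reset
        i_ext = i_tonic
        if config.beta_gain != 0.0:
            i_ext = i_tonic + config.beta_gain * np.log(p_post)
        exp_arg = np.minimum((v - prm.v_t) / prm.delta_t, 20.0)
        i_m = (-prm.g_l * (v - prm.e_l)
               + prm.g_l * prm.delta_t * np.exp(exp_arg)
               - i_w + i_ext + i_syn)
        v += dt * i_m / prm.c_m
        refractory = ref > 0
        v[refractory] = prm.v_r[refractory]
        ref = np.maximum(ref - dt, 0.0)
        i_w *= decay_w

        spiked = v >= prm.v_cut
        if spiked.any():
            v[spiked] = prm.v_r[spiked]
            i_w[spiked] += prm.b[spiked]
            ref[spiked] = prm.tau_ref[spiked]
        ring[t % ring_len] = spiked

        # (7) record
        if rec_v is not None:
            rec_v[t] = v[rec_v_ids]
        if config.record_spikes and spiked.any():
            spike_step_ids.append(np.flatnonzero(spiked))
            spike_step_t.append((t + 1) * dt)
        if t in snapshot_steps:
            snapshots.append(take_snapshot(snapshot_steps[t]))

        if (t + 1) % config.check_every == 0 and not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise SimulationError(
                f"non-finite membrane potential at neuron {bad}, "
                f"t = {(t + 1) * dt:.1f} ms")

    if spike_step_ids:
        neuron_col = np.concatenate(spike_step_ids)
        time_col = np.concatenate([
            np.full(len(ids), tt) for ids, tt in zip(spike_step_ids, spike_step_t)])
    else:
        neuron_col = np.empty(0, int)
        time_col = np.empty(0)
    spikes = pd.DataFrame({"neuron": neuron_col, "time": time_col})
    weight_snapshots = (pd.concat(snapshots, ignore_index=True)
                        if snapshots else pd.DataFrame(
                            columns=["t", "projection", "pre", "post", "w",
                                     "p_i", "p_j", "p_ij", "beta_j"]))

    voltages = (pd.DataFrame(rec_v, columns=[str(i) for i in rec_v_ids])
                if rec_v is not None else None)
    return RecordingSet(
        spikes=spikes,
        weight_snapshots=weight_snapshots,
        currents=rec_currents,
        populations=network.populations,
        cell_class=network.cell_class,
        config=config,
        voltages=voltages,
    )
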