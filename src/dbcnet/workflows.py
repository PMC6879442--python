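"""End-to-end workflows: single trials, multi-trial training summaries,
and single-cell electrophysiological characterisation.

These functions are the programmatic face of the package (the CLI wraps
them): run the default two-stimulus training protocol over independent
seeds, snapshot the initial (IWD) and learned (LWD) weight distributions,
measure population rates and the trial-averaged inhibitory current onto
MC0 pyramidal cells, and audit Dale's principle on the learned weights.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import analysis
from . import params as P
from .config import RunConfig
from .engine import RecordingSet, run
from .network import dale_violations
from .neurons import fI_curve, measure_input_resistance

__all__ = ["run_default_trial", "characterize_neuron", "reproduce"]


def run_default_trial(seed: int, config: RunConfig | None = None) -> RecordingSet:
    """One trial of the default protocol.

    ``seed`` drives the wiring, the stimuli and the noise through separate
    named streams; identical seeds give bit-identical recordings.
    """
    config = config or RunConfig()
    network = config.build_network(rng_seed=seed)
    protocol = config.build_protocol()
    engine_cfg = replace(config.engine, seed=seed)
    return run(network, protocol, engine_cfg, bcpnn=config.plasticity)


def characterize_neuron(cell: str = "dbc",
                        config: RunConfig | None = None) -> dict:
    """Electrophysiological report for one cell class.

    Returns input resistance (MOhm), passive membrane time constant (ms),
    rheobase (pA), an f-I curve, and the firing rate under the designated
    strong-stimulation current step.
    """
    config = config or RunConfig()
    if cell not in config.neurons:
        raise KeyError(f"unknown cell class {cell!r}")
    prm = config.neurons[cell]
    rheo = prm.rheobase
    currents = np.linspace(0.5 * rheo, 3.0 * rheo, 10)
    rates = fI_curve(prm, currents, duration=2000.0)
    strong = P.DBC_STRONG_STEP_PA if cell == "dbc" else 2.0 * rheo
    strong_rate = float(fI_curve(prm, [strong], duration=2000.0)[0])
    return {
        "cell": cell,
        "input_resistance_mohm": measure_input_resistance(prm),
        "membrane_time_constant_ms": prm.tau_m,
        "rheobase_pa": rheo,
        "fI_currents_pa": currents.tolist(),
        "fI_rates_hz": rates.tolist(),
        "strong_step_pa": float(strong),
        "strong_step_rate_hz": strong_rate,
    }


def _protocol_times(config: RunConfig) -> dict:
    t_iwd, t_lwd = config.engine.snapshot_times[0], config.engine.snapshot_times[-1]
    return {
        "iwd": t_iwd, "lwd": t_lwd,
        "stim0": P.STIM0_WINDOW, "stim1": P.STIM1_WINDOW,
        "pre_window": (2500.0, 3000.0), "post_window": (4000.0, P.T_END_DEFAULT),
    }


def reproduce(
    n_trials: int = 20,
    seed: int = 1,
    config: RunConfig | None = None,
    progress: bool = False,
) -> dict:
    """Train the default network over ``n_trials`` independent seeds and
    summarise the learning and inhibition readouts.

    The summary carries, averaged across trials: the IWD and LWD means of
    the three MC0-centred plastic projections (recurrent pyr->pyr within
    MC0, associative pyr MC0 -> pyr MC2, and pyr MC0 -> DBC of MC1 and of
    MC3), the stimulated DBC firing rate, the 10 ms-binned trial-averaged
    GABA current profile onto MC0 pyramidal cells with its peak during the
    competing stimulus, and a Dale's-principle audit.
    """
    config = config or RunConfig()
    times = _protocol_times(config)
    trial_seeds = [int(s) for s in
                   np.random.SeedSequence(seed).generate_state(n_trials) >> 1]

    projections = {
        "recurrent_mc0": "pyr_mc0->pyr_mc0",
        "associative_mc0_mc2": "pyr_mc0->pyr_mc2",
        "pyr_mc0_dbc_mc1": "pyr_mc0->dbc_mc1",
        "pyr_mc0_dbc_mc3": "pyr_mc0->dbc_mc3",
    }
    iwd = {k: [] for k in projections}
    lwd = {k: [] for k in projections}
    lwd_dbc_weights: list[np.ndarray] = []
    dbc_rates: list[float] = []
    profiles: list[np.ndarray] = []
    dale: list[str] = []

    for i, s in enumerate(trial_seeds):
        rec = run_default_trial(s, config)
        for key, proj in projections.items():
            iwd[key].append(analysis.weight_stats(rec, proj, times["iwd"]).mean)
            lwd[key].append(analysis.weight_stats(rec, proj, times["lwd"]).mean)
        for proj in ("pyr_mc0->dbc_mc1", "pyr_mc0->dbc_mc3"):
            lwd_dbc_weights.append(
                analysis.weight_stats(rec, proj, times["lwd"]).weights)
        dbc_rates.append(analysis.population_rate(rec, "dbc_mc0", times["stim1"]))
        profiles.append(analysis.current_profile(rec, "pyr_mc0", bin_ms=10.0))
        net = config.build_network(rng_seed=s)
        dale.extend(dale_violations(net))
        if progress:
            print(f"trial {i + 1}/{n_trials} (seed {s}) done")

    profile = np.mean(profiles, axis=0)
    t_bins = (np.arange(len(profile)) + 0.5) * 10.0

    def window_mean_abs(w):
        sel = (t_bins >= w[0]) & (t_bins <= w[1])
        return float(np.abs(profile[sel]).mean())

    def window_peak(w):
        sel = (t_bins >= w[0]) & (t_bins <= w[1])
        return float(np.abs(profile[sel]).max())

    dbc_w = np.concatenate(lwd_dbc_weights)
    return {
        "n_trials": n_trials,
        "seeds": trial_seeds,
        "iwd_mean": {k: float(np.mean(v)) for k, v in iwd.items()},
        "lwd_mean": {k: float(np.mean(v)) for k, v in lwd.items()},
        "lwd_pyr_dbc_min_weight": float(dbc_w.min()),
        "lwd_pyr_dbc_negative_fraction": float((dbc_w < 0).mean()),
        "dbc_rate_stim_hz": float(np.mean(dbc_rates)),
        "i_gaba_profile_pa": profile.tolist(),
        "i_gaba_bin_ms": 10.0,
        "i_gaba_peak_pa": window_peak(times["stim1"]),
        "i_gaba_pre_window_pa": window_mean_abs(times["pre_window"]),
        "i_gaba_post_window_pa": window_mean_abs(times["post_window"]),
        "dale_violations": dale,
    }
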