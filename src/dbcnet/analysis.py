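"""Readouts of a trained run: weight distributions, population firing
rates, and the trial-averaged inhibitory current profile.

Weight distributions are snapshotted twice by the default protocol: the
initial weight distribution (IWD) after the one-second zero-mean-noise
initialisation, and the learned weight distribution (LWD) at the end of the
run, after both training stimuli.  The inhibitory-current profile averages
the network GABA input current onto a pyramidal population over neurons,
then over independent-seed trials, in fixed-width time bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .engine import RecordingSet
from .errors import ConfigurationError

__all__ = ["WeightDistribution", "CurrentProfile", "weight_stats",
           "population_rate", "current_profile", "inhibitory_current_profile",
           "peak_magnitude"]


@dataclass
class WeightDistribution:
    projection: str
    t: float                   # snapshot time (ms)
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float                # of the raw weights, not the binned ones
    n_connections: int
    weights: np.ndarray


@dataclass
class CurrentProfile:
    population: str
    bin_ms: float
    n_trials: int
    time: np.ndarray           # bin centres (ms)
    i_gaba: np.ndarray         # trial-and-neuron mean per bin (pA, signed)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.i_gaba)


def weight_stats(
    recordings: RecordingSet,
    projection: str,
    t: float,
    bin_width: float = 0.1,
) -> WeightDistribution:
    """Distribution of the projection's plastic weights at snapshot ``t``."""
    snaps = recordings.weight_snapshots
    sel = snaps[(snaps["projection"] == projection)
                & (np.isclose(snaps["t"], t))]
    if sel.empty:
        known_t = sorted(snaps["t"].unique().tolist())
        raise ConfigurationError(
            f"no snapshot of projection {projection!r} at t = {t} ms "
            f"(snapshots at {known_t})")
    w = sel["w"].to_numpy()
    lo = np.floor(w.min() / bin_width) * bin_width
    hi = np.ceil(w.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(w, bins=edges)
    return WeightDistribution(
        projection=projection, t=t, bin_edges=edges, counts=counts,
        mean=float(w.mean()), n_connections=len(w), weights=w)


def population_rate(
    recordings: RecordingSet,
    population: str,
    window: tuple[float, float],
) -> float:
    """Mean firing rate (Hz): spikes per neuron per second over ``window``."""
    ids = recordings.populations.get(population)
    if ids is None:
        raise ConfigurationError(f"unknown population {population!r}")
    if len(ids) == 0:
        raise ConfigurationError(f"population {population!r} is empty")
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError("empty rate window")
    times = recordings.spike_times(ids)
    n_spikes = int(np.count_nonzero((times > t0) & (times <= t1)))
    return n_spikes / len(ids) / ((t1 - t0) / 1000.0)


def current_profile(
    recordings: RecordingSet,
    population: str,
    bin_ms: float = 10.0,
) -> np.ndarray:
    """Single-trial binned profile: the population-mean network GABA input
    current (pA), averaged within consecutive ``bin_ms`` windows."""
    rec = recordings.currents.get(population)
    if rec is None:
        raise ConfigurationError(
            f"no current recording for population {population!r}")
    per_step = rec.i_gaba.mean(axis=1)           # over neurons
    steps_per_bin = int(round(bin_ms / rec.dt))
    if steps_per_bin <= 0 or len(per_step) % steps_per_bin:
        raise ConfigurationError(
            f"bin width {bin_ms} ms does not tile the recording")
    return per_step.reshape(-1, steps_per_bin).mean(axis=1)


def inhibitory_current_profile(
    run_fn: Callable[[int], RecordingSet],
    population: str = "pyr_mc0",
    n_trials: int = 20,
    bin_ms: float = 10.0,
    seeds=None,
) -> CurrentProfile:
    """Trial-averaged inhibitory input current onto ``population``.

    ``run_fn(seed)`` must rerun the identical protocol with an independent
    random seed and record the population's currents.  Averaging is over
    neurons within each trial, then over trials.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    seeds = list(seeds) if seeds is not None else list(range(n_trials))
    profiles = []
    for seed in seeds[:n_trials]:
        rec = run_fn(seed)
        profiles.append(current_profile(rec, population, bin_ms))
    mean = np.mean(profiles, axis=0)
    time = (np.arange(len(mean)) + 0.5) * bin_ms
    return CurrentProfile(population=population, bin_ms=bin_ms,
                          n_trials=len(profiles), time=time, i_gaba=mean)


def peak_magnitude(profile: CurrentProfile, window: tuple[float, float]) -> float:
    """Maximum binned current magnitude (pA) within the time window."""
    sel = (profile.time >= window[0]) & (profile.time <= window[1])
    if not sel.any():
        raise ConfigurationError("window contains no bins")
    return float(profile.magnitude[sel].max())
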