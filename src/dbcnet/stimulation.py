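"""Training stimuli and background noise.

The default protocol trains the two attractors of the default network:

* STIM0 (1000-2000 ms) drives the pyramidal cells of the first coactive
  group (MC0, MC2) *and the DBCs of the competing group* (MC1, MC3).
* STIM1 (3000-4000 ms) drives the pyramidal cells of MC1, MC3 and the DBCs
  of MC0, MC2.
* Zero-mean noise (ZMN) is active throughout.

Co-driving each stimulus with the DBCs of the competing columns is the key
design feature: pyramidal cells and the competing columns' DBCs then fire
together, so the Hebbian-Bayesian rule learns *positive* pyr->DBC weights
and inhibition between competing columns becomes purely disynaptic.

Stimuli are independent homogeneous Poisson trains per target neuron,
delivered as static conductance events onto AMPA receptors.  The ZMN is a
pair of independent Poisson sources per neuron, one exciting and one
inhibiting, with the inhibitory conductance amplitude scaled by the
driving-force ratio at a reference potential so the mean injected current
is approximately zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as P
from .errors import ConfigurationError
from .network import NetworkSpec, competing_mcs

__all__ = ["StimulusSpec", "NoiseSpec", "Protocol", "default_protocol",
           "generate_spike_train"]


@dataclass(frozen=True)
class StimulusSpec:
    """A selective Poisson stimulus.

    ``targets`` is a tuple of ``(cell_class, mc_id)`` pairs; every neuron of
    each targeted population receives an independent Poisson train at
    ``rate`` Hz inside ``window`` (ms), each event adding ``weight`` nS to
    the target's AMPA conductance.
    """

    label: str
    rate: float
    window: tuple[float, float]
    targets: tuple[tuple[str, int], ...]
    weight: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError(f"stimulus {self.label}: rate must be >= 0")
        if self.window[1] < self.window[0]:
            raise ConfigurationError(f"stimulus {self.label}: empty window")


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean background noise: two independent Poisson conductance
    sources per neuron.  ``g_inh`` defaults to ``g_exc`` scaled by the
    excitatory/inhibitory driving-force ratio at ``v_ref`` so that the mean
    current vanishes there.  ``class_scale`` multiplies both amplitudes per
    cell class: the background bombardment a cell receives scales with its
    size and synapse count, so the small double bouquet cells get a reduced
    share of the noise."""

    rate: float = P.ZMN_RATE         # Hz per source per neuron
    g_exc: float = P.ZMN_G_EXC       # nS per excitatory event
    g_inh: float | None = None       # nS per inhibitory event
    v_ref: float = P.ZMN_V_REF       # mV
    class_scale: tuple[tuple[str, float], ...] = P.ZMN_CLASS_SCALE

    def __post_init__(self) -> None:
        if self.rate < 0 or self.g_exc < 0:
            raise ConfigurationError("noise rate and amplitudes must be >= 0")
        if any(s < 0 for _, s in self.class_scale):
            raise ConfigurationError("noise class scales must be >= 0")

    @property
    def g_inh_effective(self) -> float:
        if self.g_inh is not None:
            return self.g_inh
        drive_exc = P.E_AMPA - self.v_ref
        drive_inh = self.v_ref - P.E_GABA
        return self.g_exc * drive_exc / drive_inh


@dataclass(frozen=True)
class Protocol:
    stimuli: tuple[StimulusSpec, ...]
    noise: NoiseSpec = field(default_factory=NoiseSpec)


def default_protocol(
    spec: NetworkSpec | None = None,
    rate: float = P.STIM_RATE,
    weight_pyr: float = P.STIM_WEIGHT_PYR,
    weight_dbc: float = P.STIM_WEIGHT_DBC,
    noise: NoiseSpec | None = None,
) -> Protocol:
    """The two-stimulus training protocol for the given network spec.

    Each stimulus targets the pyramidal cells of one coactive group and the
    DBCs of the other; swapping the two groups in the spec swaps the two
    stimuli's target sets exactly.
    """
    spec = spec or NetworkSpec()
    if len(spec.coactive_groups) != 2:
        raise ConfigurationError(
            "default protocol requires exactly two coactive groups")
    windows = (P.STIM0_WINDOW, P.STIM1_WINDOW)
    stimuli: list[StimulusSpec] = []
    for idx, (group, window) in enumerate(zip(spec.coactive_groups, windows)):
        pyr_targets = tuple(("pyr", mc) for mc in group)
        dbc_targets = tuple(
            sorted({("dbc", c) for mc in group for c in competing_mcs(spec, mc)}))
        stimuli.append(StimulusSpec(
            label=f"STIM{idx}", rate=rate, window=window,
            targets=pyr_targets, weight=weight_pyr))
        stimuli.append(StimulusSpec(
            label=f"STIM{idx}", rate=rate, window=window,
            targets=dbc_targets, weight=weight_dbc))
    return Protocol(stimuli=tuple(stimuli), noise=noise or NoiseSpec())


def generate_spike_train(
    rate: float,
    window: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Event times (ms) of a homogeneous Poisson process inside ``window``.

    Draws the Poisson count for the window, then places the events
    uniformly (the conditional law of a homogeneous Poisson process).
    """
    t0, t1 = window
    if t1 < t0 or rate < 0:
        raise ConfigurationError("invalid rate or window")
    duration_s = (t1 - t0) / 1000.0
    n = rng.poisson(rate * duration_s)
    return np.sort(t0 + rng.random(n) * (t1 - t0))
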