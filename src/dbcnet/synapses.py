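"""Conductance-based AMPA/GABA synapses with short-term depression.

Each synapse contributes an exponentially decaying conductance g(t); the
current onto neuron j is the Ohmic sum

    I_syn_j = -sum_syn g_ij(t) (V_j - E_rev^syn)

split by receptor (AMPA depolarizing below its reversal, GABA
hyperpolarizing above its reversal).  Plastic AMPA synapses additionally
carry a Tsodyks-Markram depression resource x in (0, 1]:

    dx/dt = (1 - x)/tau_rec - U x sum_sp delta(t - t_sp)

i.e. each presynaptic spike consumes a fraction U of the resource, which
then recovers exponentially.  The conductance increment of a spike is
g_gain * max(w, 0) * U * x for a plastic synapse (negative learned weights
are clipped at the conductance mapping, enforcing Dale's principle
mechanically) and g_gain * w_static for a static one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "SynapseParams",
    "SynapseState",
    "SynapticCurrent",
    "synapse_decay",
    "on_presynaptic_spike",
    "synaptic_current",
]


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic and depression parameters of one projection's synapses.

    ``e_rev``/``tau_syn`` select the receptor (0 mV / -80 mV reversal and a
    5 ms decay for both AMPA and GABA by default), ``u``/``tau_rec`` the
    Tsodyks-Markram constants, ``delay`` the conduction delay and ``g_gain``
    the conductance per unit weight.
    """

    e_rev: float = 0.0        # mV
    tau_syn: float = 5.0      # ms
    u: float = 0.25           # utilization fraction
    tau_rec: float = 500.0    # ms
    delay: float = 1.5        # ms
    g_gain: float = 1.0       # nS per unit weight
    depressing: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.u <= 1.0):
            raise ValueError("require 0 < u <= 1")
        if self.tau_rec <= 0 or self.tau_syn <= 0:
            raise ValueError("tau_rec and tau_syn must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


@dataclass
class SynapseState:
    """Conductance and depression resource, vectorised over synapses."""

    g: np.ndarray       # instantaneous conductance (nS), >= 0
    x_dep: np.ndarray   # depression resource, in (0, 1]

    @classmethod
    def rest(cls, n: int = 1) -> "SynapseState":
        return cls(g=np.zeros(n, dtype=float), x_dep=np.ones(n, dtype=float))


def synapse_decay(state: SynapseState, params: SynapseParams, dt: float) -> SynapseState:
    """Relax the state over ``dt`` ms with no presynaptic spikes.

    The conductance decays as exp(-dt/tau_syn); the depression resource
    recovers toward 1 exactly, x(t+dt) = 1 - (1 - x(t)) exp(-dt/tau_rec).
    ``dt = 0`` is the identity.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    g = state.g * np.exp(-dt / params.tau_syn)
    x = 1.0 - (1.0 - state.x_dep) * np.exp(-dt / params.tau_rec)
    return SynapseState(g=g, x_dep=x)


def on_presynaptic_spike(
    state: SynapseState,
    params: SynapseParams,
    weight: np.ndarray | float,
) -> SynapseState:
    """Apply the jump condition of a (delay-adjusted) presynaptic spike.

    Depressing synapses: g += g_gain * max(weight, 0) * U * x, then
    x *= (1 - U) -- the resource is consumed whether or not the clipped
    weight transmitted anything.  Static synapses: g += g_gain * weight
    with no resource dynamics.
    """
    weight = np.asarray(weight, dtype=float)
    if params.depressing:
        g = state.g + params.g_gain * np.maximum(weight, 0.0) * params.u * state.x_dep
        x = state.x_dep * (1.0 - params.u)
    else:
        g = state.g + params.g_gain * weight
        x = state.x_dep
    return SynapseState(g=g, x_dep=x)


class SynapticCurrent(NamedTuple):
    total: np.ndarray
    ampa: np.ndarray
    gaba: np.ndarray


def synaptic_current(
    g_ampa: np.ndarray | float,
    g_gaba: np.ndarray | float,
    v_m: np.ndarray | float,
    e_ampa: float = 0.0,
    e_gaba: float = -80.0,
) -> SynapticCurrent:
    """Total synaptic current (pA) plus its AMPA and GABA partial sums.

    Sign convention: a positive return value depolarizes, so the AMPA term
    is positive for V below its reversal and the GABA term is negative
    (hyperpolarizing) for V above E_GABA.  The GABA partial sum is exposed
    separately because the disynaptic-inhibition analysis tracks it.
    """
    i_ampa = -np.asarray(g_ampa, dtype=float) * (np.asarray(v_m) - e_ampa)
    i_gaba = -np.asarray(g_gaba, dtype=float) * (np.asarray(v_m) - e_gaba)
    return SynapticCurrent(total=i_ampa + i_gaba, ampa=i_ampa, gaba=i_gaba)


def periodic_train_steady_state(u: float, tau_rec: float, interval: float) -> float:
    """Closed-form steady-state resource just before each spike of a
    periodic train with the given inter-spike interval (ms).

    x* = (1 - e^(-dt/tau_rec)) / (1 - (1 - U) e^(-dt/tau_rec))
    """
    decay = np.exp(-interval / tau_rec)
    return float((1.0 - decay) / (1.0 - (1.0 - u) * decay))
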