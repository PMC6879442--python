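"""Adaptive exponential integrate-and-fire (AdEx) point neurons.

The membrane equation is

    C_m dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_t)/Delta_T)
                - I_w + I_ext + I_syn

with a spike-triggered adaptation current

    dI_w/dt = -I_w / tau_w,    I_w <- I_w + b at each spike.

Subthreshold adaptation (the usual ``a (V - E_L)`` term) is deliberately
absent: the cell classes modelled here (pyramidal, basket, double bouquet)
only need spike-triggered adaptation, and dropping the subthreshold term
keeps the resting potential exactly at E_L.

Units follow the common point-neuron convention: mV, ms, pA, pF, nS.  Note
that pA/pF = mV/ms and nS * mV = pA, so no unit conversion factors appear.

The functions are vectorised: a :class:`NeuronState` holds arrays over a
population, and scalar use is just the length-1 case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeasurementError

__all__ = [
    "NeuronParams",
    "NeuronState",
    "adex_step",
    "detect_and_reset",
    "measure_input_resistance",
    "fI_curve",
]

# Exponential argument above which the upstroke term saturates.  Once
# (V - V_t)/Delta_T reaches this value the neuron fires within the step
# regardless, so the clip only guards against float overflow.
_EXP_ARG_MAX = 20.0


@dataclass(frozen=True)
class NeuronParams:
    """AdEx parameter set for one cell class.

    Parameters
    ----------
    c_m : membrane capacitance (pF)
    g_l : leak conductance (nS)
    e_l : leak reversal potential (mV)
    v_t : spike threshold of the exponential term (mV)
    delta_t : upstroke slope factor (mV)
    b : spike-triggered adaptation increment (pA)
    tau_w : adaptation recovery time constant (ms)
    v_r : post-spike reset potential (mV)
    tau_ref : absolute refractory period (ms)
    v_cut : numerical spike-detection cutoff (mV); defaults to
        ``v_t + 5 * delta_t``, past which the upstroke is effectively
        instantaneous on the integration grid.
    """

    c_m: float
    g_l: float
    e_l: float
    v_t: float
    delta_t: float
    b: float
    tau_w: float
    v_r: float
    tau_ref: float
    v_cut: float | None = None

    def __post_init__(self) -> None:
        if self.v_cut is None:
            object.__setattr__(self, "v_cut", self.v_t + 5.0 * self.delta_t)
        vals = [self.c_m, self.g_l, self.e_l, self.v_t, self.delta_t,
                self.b, self.tau_w, self.v_r, self.tau_ref, self.v_cut]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("neuron parameters must be finite")
        if self.c_m <= 0 or self.g_l <= 0 or self.tau_w <= 0 or self.delta_t <= 0:
            raise ValueError("c_m, g_l, tau_w and delta_t must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if not (self.v_r <= self.v_t < self.v_cut):
            raise ValueError("require v_r <= v_t < v_cut")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m / g_L (ms)."""
        return self.c_m / self.g_l

    @property
    def rheobase(self) -> float:
        """Minimal constant current (pA) with no subthreshold fixed point.

        The steady-state I-V curve I(V) = g_L (V - E_L) - g_L Delta_T
        exp((V - V_t)/Delta_T) attains its maximum at V = V_t, giving
        I_rh = g_L (V_t - E_L - Delta_T).
        """
        return self.g_l * (self.v_t - self.e_l - self.delta_t)


@dataclass
class NeuronState:
    """Dynamical state of a population of identical AdEx neurons."""

    v: np.ndarray          # membrane potential (mV)
    i_w: np.ndarray        # adaptation current (pA)
    ref_ms: np.ndarray     # remaining refractory time (ms)

    @classmethod
    def resting(cls, params: NeuronParams, n: int = 1) -> "NeuronState":
        return cls(
            v=np.full(n, params.e_l, dtype=float),
            i_w=np.zeros(n, dtype=float),
            ref_ms=np.zeros(n, dtype=float),
        )

    def copy(self) -> "NeuronState":
        return NeuronState(self.v.copy(), self.i_w.copy(), self.ref_ms.copy())


def adex_step(
    state: NeuronState,
    params: NeuronParams,
    i_syn: np.ndarray | float,
    i_ext: np.ndarray | float,
    dt: float,
) -> NeuronState:
    """Advance the membrane equation by one forward-Euler step of ``dt`` ms.

    The adaptation current decays exactly (``exp(-dt/tau_w)``); the membrane
    potential uses forward Euler with the exponential term clipped to avoid
    overflow.  Neurons inside their refractory period stay clamped at the
    reset potential while their refractory clock runs down.  No spike is
    emitted here; see :func:`detect_and_reset`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, i_w = state.v, state.i_w
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(i_w))):
        raise ValueError("non-finite neuron state")

    exp_arg = np.minimum((v - params.v_t) / params.delta_t, _EXP_ARG_MAX)
    i_m = (
        -params.g_l * (v - params.e_l)
        + params.g_l * params.delta_t * np.exp(exp_arg)
        - i_w
        + i_ext
        + i_syn
    )
    v_new = v + dt * i_m / params.c_m
    i_w_new = i_w * np.exp(-dt / params.tau_w)

    refractory = state.ref_ms > 0
    v_new = np.where(refractory, params.v_r, v_new)
    ref_new = np.maximum(state.ref_ms - dt, 0.0)
    return NeuronState(v=v_new, i_w=i_w_new, ref_ms=ref_new)


def detect_and_reset(
    state: NeuronState, params: NeuronParams
) -> tuple[NeuronState, np.ndarray]:
    """Detect threshold crossings and apply the AdEx reset.

    Where ``v >= v_cut``: the membrane is reset to ``v_r``, the adaptation
    current jumps by ``b`` and the refractory clock is loaded with
    ``tau_ref``.  Returns the updated state and a boolean spike array.
    """
    spiked = state.v >= params.v_cut
    if not np.any(spiked):
        return state, spiked
    v = np.where(spiked, params.v_r, state.v)
    i_w = np.where(spiked, state.i_w + params.b, state.i_w)
    ref = np.where(spiked, params.tau_ref, state.ref_ms)
    return NeuronState(v=v, i_w=i_w, ref_ms=ref), spiked


def _simulate_current_step(
    params: NeuronParams, i_ext: np.ndarray, duration: float, dt: float
) -> tuple[NeuronState, np.ndarray]:
    """Integrate isolated neurons under constant current; count spikes."""
    i_ext = np.atleast_1d(np.asarray(i_ext, dtype=float))
    state = NeuronState.resting(params, len(i_ext))
    n_steps = int(round(duration / dt))
    counts = np.zeros(len(i_ext), dtype=int)
    for _ in range(n_steps):
        state = adex_step(state, params, 0.0, i_ext, dt)
        state, spiked = detect_and_reset(state, params)
        counts += spiked
    return state, counts


def measure_input_resistance(
    params: NeuronParams,
    i_step: float = -5.0,
    settle: float = 1000.0,
    dt: float = 0.1,
) -> float:
    """Input resistance (MOhm) from a small hyperpolarizing current step.

    Simulates the cell to steady state with and without the step and
    returns Delta V / I.  For small deflections around rest this approaches
    1/g_L (658 MOhm for the double bouquet cell defaults).

    Raises
    ------
    MeasurementError
        If the step drives the membrane above threshold, where the
        measurement is no longer a passive one.
    """
    if i_step == 0:
        raise ValueError("i_step must be non-zero")
    state, counts = _simulate_current_step(
        params, np.array([0.0, i_step]), settle, dt
    )
    if counts.any() or state.v[1] > params.v_t:
        raise MeasurementError(
            "current step drove the membrane above threshold; "
            "use a smaller or hyperpolarizing step"
        )
    dv = state.v[1] - state.v[0]
    return float(dv / i_step * 1e3)  # mV/pA = GOhm -> MOhm


def fI_curve(
    params: NeuronParams,
    currents,
    duration: float = 2000.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Mean firing rate (Hz) for each constant current level (pA).

    Each level is simulated independently from rest for ``duration`` ms;
    rates are spike counts divided by the duration.  For AdEx the curve is
    non-decreasing in the injected current.
    """
    currents = np.atleast_1d(np.asarray(currents, dtype=float))
    if currents.size == 0:
        raise ValueError("currents must be non-empty")
    if duration <= 0:
        raise ValueError("duration must be positive")
    _, counts = _simulate_current_step(params, currents, duration, dt)
    return counts / (duration / 1000.0)
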