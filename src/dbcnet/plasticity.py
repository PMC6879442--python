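"""Spike-based BCPNN (Bayesian Confidence Propagation) learning rule.

The rule filters the pre- and postsynaptic spike trains S_i, S_j through a
fast exponential stage (Z traces, time constant tau_z),

    tau_z dZ/dt = S / (f_max * t_spike) - Z + eps,

where a spike contributes a rectangular pulse of height 1/(f_max*t_spike)
lasting t_spike, so each spike adds ~1/(f_max*tau_z) to Z.  A slower stage
(P traces, time constant tau_p) estimates activation and coactivation
probabilities,

    tau_p dP_i/dt  = kappa (Z_i - P_i)        (same for P_j)
    tau_p dP_ij/dt = kappa (Z_ij - P_ij),     Z_ij := Z_i * Z_j,

and the synaptic weight and intrinsic excitability are the log-odds

    w_ij = log(P_ij / (P_i * P_j)),    beta_j = log(P_j).

kappa gates learning: kappa = 0 freezes all P traces (and therefore the
weights) exactly; the full protocol here runs with kappa = 1 throughout.
The coactivation trace Z_ij is the product of the two Z traces -- the
delayed-reward eligibility (E-trace) stage of the rule family is bypassed.

Two co-activated neurons drive P_ij above P_i*P_j and learn a positive
weight; independent firing gives w -> 0; anti-correlated firing gives
w < 0 (which the conductance mapping in :mod:`dbcnet.synapses` clips).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "BcpnnParams",
    "BcpnnState",
    "update_z",
    "update_p",
    "compute_weight_bias",
    "bias_current",
    "filter_traces",
]


@dataclass(frozen=True)
class BcpnnParams:
    """BCPNN trace parameters.

    tau_z : fast (Z) trace time constant, ms; pre and post share it.
    tau_p : slow (P) probability-trace time constant, ms; must exceed tau_z.
    f_max : maximal neuronal spike rate (Hz) used to normalise activity.
    eps : lowest attainable probability estimate (floor of the Z traces).
    t_spike : spike-pulse duration (ms); defaults to the integration step.
    kappa : learning-rate gate; 0 freezes learning, 1 is full speed.
    """

    tau_z: float = 5.0
    tau_p: float = 2000.0
    f_max: float = 20.0
    eps: float = 0.01
    t_spike: float = 0.1
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_z <= 0 or self.t_spike <= 0 or self.f_max <= 0:
            raise ValueError("tau_z, t_spike and f_max must be positive")
        if self.tau_p <= self.tau_z:
            raise ValueError("require tau_p > tau_z")
        if not (0.0 < self.eps < 1.0):
            raise ValueError("require 0 < eps < 1")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    @property
    def spike_pulse(self) -> float:
        """Height of the rectangular spike pulse, 1/(f_max * t_spike).

        f_max is in Hz and t_spike in ms, hence the 1e-3.
        """
        return 1.0 / (self.f_max * 1e-3 * self.t_spike)


@dataclass
class BcpnnState:
    """Traces of one (vectorised) pre/post pair.

    ``pulse_i``/``pulse_j`` carry the remaining spike-pulse time so that
    t_spike > dt is integrated exactly as a rectangular pulse rather than
    an instantaneous jump.
    """

    z_i: np.ndarray
    z_j: np.ndarray
    p_i: np.ndarray
    p_j: np.ndarray
    p_ij: np.ndarray
    pulse_i: np.ndarray
    pulse_j: np.ndarray

    @classmethod
    def initial(cls, params: BcpnnParams, n: int = 1) -> "BcpnnState":
        """Symmetric low-activity initialisation: Z and P at the eps floor,
        P_ij at eps**2, so that w = 0 and the state is a fixed point of the
        spike-free dynamics."""
        e = params.eps
        return cls(
            z_i=np.full(n, e), z_j=np.full(n, e),
            p_i=np.full(n, e), p_j=np.full(n, e),
            p_ij=np.full(n, e * e),
            pulse_i=np.zeros(n), pulse_j=np.zeros(n),
        )

    def copy(self) -> "BcpnnState":
        return BcpnnState(*(a.copy() for a in
                            (self.z_i, self.z_j, self.p_i, self.p_j,
                             self.p_ij, self.pulse_i, self.pulse_j)))


def _z_step(z, pulse, spikes, params: BcpnnParams, dt: float):
    pulse = np.where(spikes, params.t_spike, pulse)
    drive = np.where(pulse > 0, params.spike_pulse, 0.0)
    # active fraction of the step, exact for t_spike = k*dt
    frac = np.clip(pulse / dt, 0.0, 1.0)
    z = z + (dt / params.tau_z) * (drive * frac + params.eps - z)
    pulse = np.maximum(pulse - dt, 0.0)
    return z, pulse


def update_z(
    state: BcpnnState,
    params: BcpnnParams,
    spike_pre: np.ndarray | bool,
    spike_post: np.ndarray | bool,
    dt: float,
) -> BcpnnState:
    """Advance the Z traces one step; spikes start a rectangular pulse."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = state.copy()
    s.z_i, s.pulse_i = _z_step(s.z_i, s.pulse_i, np.asarray(spike_pre, bool), params, dt)
    s.z_j, s.pulse_j = _z_step(s.z_j, s.pulse_j, np.asarray(spike_post, bool), params, dt)
    return s


def update_p(state: BcpnnState, params: BcpnnParams, dt: float) -> BcpnnState:
    """Relax the P traces toward Z_i, Z_j and Z_ij = Z_i*Z_j at rate
    kappa/tau_p.  With kappa = 0 the state is returned unchanged."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.kappa == 0:
        return state
    a = params.kappa * dt / params.tau_p
    s = state.copy()
    s.p_i = s.p_i + a * (s.z_i - s.p_i)
    s.p_j = s.p_j + a * (s.z_j - s.p_j)
    s.p_ij = s.p_ij + a * (s.z_i * s.z_j - s.p_ij)
    return s


def compute_weight_bias(state: BcpnnState) -> tuple[np.ndarray, np.ndarray]:
    """Log-odds weight w = log(P_ij/(P_i P_j)) and bias beta = log(P_j).

    Raises ``ValueError`` on non-positive P traces; the eps floor makes
    that unreachable from a valid initial state.
    """
    if (np.any(state.p_i <= 0) or np.any(state.p_j <= 0)
            or np.any(state.p_ij <= 0)):
        raise ValueError("P traces must be positive to take logarithms")
    w = np.log(state.p_ij / (state.p_i * state.p_j))
    beta = np.log(state.p_j)
    return w, beta


def bias_current(beta_j: np.ndarray | float, beta_gain: float) -> np.ndarray | float:
    """Intrinsic-excitability current beta_gain * beta_j (pA).

    beta_gain = 0 (the default configuration) disables bias injection while
    the bias itself is still computed and recorded.
    """
    return beta_gain * beta_j


def filter_traces(
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: BcpnnParams,
    dt: float,
) -> dict[str, np.ndarray]:
    """Offline trace cascade for whole spike-count arrays (one entry per
    step).  Uses the same discrete recursion as the stepwise updates with
    t_spike = dt, evaluated with ``scipy.signal.lfilter`` for speed; handy
    for long statistical tests and examples.

    Returns arrays ``z_i, z_j, p_i, p_j, p_ij, w, beta`` over time.
    """
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post spike arrays must have equal length")
    p = BcpnnParams(tau_z=params.tau_z, tau_p=params.tau_p, f_max=params.f_max,
                    eps=params.eps, t_spike=dt, kappa=params.kappa)
    az = dt / p.tau_z
    ap = p.kappa * dt / p.tau_p

    def first_order(x, a, y0):
        # y[k] = (1-a) y[k-1] + a x[k], y[-1] = y0
        return lfilter([a], [1.0, -(1.0 - a)], x, zi=[(1.0 - a) * y0])[0]

    z_i = first_order(p.eps + pre * p.spike_pulse, az, p.eps)
    z_j = first_order(p.eps + post * p.spike_pulse, az, p.eps)
    p_i = first_order(z_i, ap, p.eps) if ap > 0 else np.full_like(z_i, p.eps)
    p_j = first_order(z_j, ap, p.eps) if ap > 0 else np.full_like(z_j, p.eps)
    p_ij = (first_order(z_i * z_j, ap, p.eps ** 2)
            if ap > 0 else np.full_like(z_i, p.eps ** 2))
    w = np.log(p_ij / (p_i * p_j))
    beta = np.log(p_j)
    return {"z_i": z_i, "z_j": z_j, "p_i": p_i, "p_j": p_j, "p_ij": p_ij,
            "w": w, "beta": beta}
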