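"""Frozen default parameters of the columnar microcircuit.

Everything a run needs that is not derived at build time lives here, in one
place: per-class AdEx parameter sets, receptor constants, per-projection
synapse descriptors, BCPNN constants, and the stimulation/noise amplitudes.
The double bouquet cell (DBC) electrophysiology is constrained by in-vitro
characterisations (high input resistance ~660 MOhm, low capacitance,
resting potential -76 mV, threshold -44 mV, mild adaptation, sustained
firing at 43 +/- 13 Hz under strong stimulation); pyramidal and basket cell
sets are conventional cortical layer II/III values from the model lineage.

The stimulation, noise and static-weight amplitudes were calibrated once so
that the default protocol reproduces the reference operating points
(stimulated DBC rate inside 43 +/- 13 Hz, learned weight means near
1.7/1.3/0.5, peak inhibitory current near 220 pA) and are frozen here; see
docs/methods.md for the calibration account.
"""

from __future__ import annotations

from .neurons import NeuronParams
from .plasticity import BcpnnParams

# --------------------------------------------------------------------------
# Receptor constants (shared across projections)
E_AMPA = 0.0      # mV
E_GABA = -80.0    # mV
TAU_AMPA = 5.0    # ms
TAU_GABA = 5.0    # ms

# --------------------------------------------------------------------------
# Cell classes
DBC = NeuronParams(
    c_m=15.0,      # pF
    g_l=1.52,      # nS  (consistent with the 660 MOhm input resistance)
    e_l=-76.0,     # mV
    v_t=-44.0,     # mV
    delta_t=1.0,   # mV
    b=3.0,         # pA  (small adaptation)
    tau_w=200.0,   # ms
    v_r=-60.0,     # mV
    tau_ref=2.0,   # ms
)

PYRAMIDAL = NeuronParams(
    c_m=280.0,
    g_l=14.0,
    e_l=-70.0,
    v_t=-55.0,
    delta_t=3.0,
    b=45.0,
    tau_w=300.0,
    v_r=-60.0,
    tau_ref=5.0,
)

BASKET = NeuronParams(
    c_m=50.0,
    g_l=10.0,
    e_l=-70.0,
    v_t=-53.0,
    delta_t=1.0,
    b=0.0,
    tau_w=100.0,
    v_r=-67.0,
    tau_ref=1.0,
)

NEURON_DEFAULTS: dict[str, NeuronParams] = {
    "pyr": PYRAMIDAL,
    "basket": BASKET,
    "dbc": DBC,
}

# --------------------------------------------------------------------------
# BCPNN constants.  tau_z = 5 ms and kappa = 1 are the rule's stated
# operating point; f_max, eps and tau_p are the calibrated normalisation.
BCPNN_DEFAULTS = BcpnnParams(
    tau_z=5.0,
    tau_p=2000.0,
    f_max=20.0,
    eps=0.026,
    t_spike=0.1,
    kappa=1.0,
)

# Intrinsic-excitability bias gain (pA per log unit); biases are recorded
# but not injected by default.
BETA_GAIN = 0.0

# --------------------------------------------------------------------------
# Per-projection synapse descriptors.  Keys are projection kinds produced by
# the network builder.  "weight" is the static weight (unused for plastic
# projections); "g_gain" maps a unit BCPNN weight to nS.
PROJECTION_DEFAULTS: dict[str, dict] = {
    # plastic, depressing AMPA
    "pyr_pyr_recurrent": dict(receptor="ampa", plastic=True, depressing=True,
                              weight=0.0, g_gain=0.6, u=0.25, tau_rec=500.0),
    "pyr_pyr_associative": dict(receptor="ampa", plastic=True, depressing=True,
                                weight=0.0, g_gain=0.6, u=0.25, tau_rec=500.0),
    "pyr_dbc": dict(receptor="ampa", plastic=True, depressing=True,
                    weight=0.0, g_gain=0.25, u=0.25, tau_rec=500.0),
    # static
    "pyr_basket": dict(receptor="ampa", plastic=False, depressing=False,
                       weight=3.5, g_gain=1.0, u=0.25, tau_rec=500.0),
    "basket_pyr": dict(receptor="gaba", plastic=False, depressing=False,
                       weight=16.0, g_gain=1.0, u=0.25, tau_rec=500.0),
    "dbc_pyr": dict(receptor="gaba", plastic=False, depressing=False,
                    weight=14.0, g_gain=1.0, u=0.25, tau_rec=500.0),
}

# --------------------------------------------------------------------------
# Stimulation protocol amplitudes (Poisson generator rate in Hz, synaptic
# weights in nS onto AMPA receptors) and zero-mean background noise.
STIM_RATE = 600.0          # Hz per target neuron
STIM_WEIGHT_PYR = 5.0      # nS
STIM_WEIGHT_DBC = 0.27     # nS
STIM0_WINDOW = (1000.0, 2000.0)   # ms
STIM1_WINDOW = (3000.0, 4000.0)   # ms

ZMN_RATE = 100.0           # Hz, each of the excitatory/inhibitory sources
ZMN_G_EXC = 4.2            # nS per event
ZMN_V_REF = -70.0          # mV, potential at which the mean current is zero
# relative noise amplitude per cell class (small cells receive fewer
# background synapses)
ZMN_CLASS_SCALE = (("pyr", 1.0), ("basket", 0.7), ("dbc", 0.25))

# Tonic depolarizing drive (pA) maintaining the DBCs' characteristic
# sustained spiking between stimuli.
TONIC_CURRENT = (("dbc", 70.0),)

# Current step used for the "strong stimulation" firing-rate check of the
# DBC model (pA); chosen to land the rate near the middle of the reported
# 43 +/- 13 Hz band.
DBC_STRONG_STEP_PA = 77.0

T_END_DEFAULT = 4500.0     # ms, covers both stimuli plus readout tail
SNAPSHOT_TIMES = (1000.0, 4500.0)   # IWD and LWD readouts
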