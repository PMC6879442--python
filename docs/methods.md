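# Methods

`dbcnet` simulates a reduced cortical layer II/III microcircuit in which
two hypercolumns (HCs), each containing two minicolumns (MCs) of pyramidal
cells, learn two competing stimulus patterns under a Hebbian-Bayesian
(BCPNN) plasticity rule, with *all* inhibition between competing
minicolumns delivered disynaptically: by basket cells inside a hypercolumn
and by double bouquet cells (DBCs) within and between hypercolumns.  The
point of the architecture is Dale's principle: excitatory synapses never
need to learn negative weights, because competition is carried by learned
excitation onto inhibitory interneurons.

## Neuron model

All cells are adaptive exponential integrate-and-fire (AdEx) point neurons:

    C_m dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_t)/Δ_T) - I_w + I_ext + I_syn
    dI_w/dt   = -I_w/τ_w,   I_w ← I_w + b at each spike

with reset to `V_r`, an absolute refractory clamp `τ_ref`, and no
subthreshold adaptation.  A spike is registered when V crosses the
numerical cutoff `V_cut = V_t + 5 Δ_T`; past that point the upstroke is
much faster than the integration step, so the exact cutoff is immaterial
(the exponential argument is also clipped to avoid float overflow).
Integration is forward Euler at dt = 0.1 ms (the adaptation current decays
exactly); tests pin the accuracy against dt/10 reference runs.

The DBC parameter set follows in-vitro characterisations of these cells:
C_m = 15 pF, g_L = 1.52 nS, E_L = −76 mV, V_t = −44 mV, Δ_T = 1 mV,
b = 3 pA, τ_w = 200 ms, V_r = −60 mV, τ_ref = 2 ms.  Note the leak unit:
only g_L in nanosiemens is consistent with the cell's ~660 MΩ input
resistance (1/1.52 nS = 658 MΩ); a picosiemens reading would put the input
resistance at 658 GΩ.  The resulting model has rheobase ≈ 47 pA, passive
membrane time constant 9.9 ms (within the reported 17.1 ± 7.7 ms window),
and fires at ~43 Hz under a 77 pA step — the middle of the 43 ± 13 Hz band
reported for strongly stimulated DBCs.  Pyramidal (C_m 280 pF, g_L 14 nS,
E_L −70, V_t −55, Δ_T 3, b 45 pA, τ_w 300 ms) and basket parameters
(C_m 50 pF, g_L 10 nS, V_t −53, Δ_T 1, b 0) are conventional cortical
values for regular-spiking and fast-spiking cells; the fast basket membrane
(τ_m = 5 ms) makes the winner-take-all loop track pyramidal volleys
sharply, which matters for learning (below).

## Synapses

Conductance-based AMPA (E_rev = 0 mV) and GABA (E_rev = −80 mV) synapses
with single-exponential kernels (τ = 5 ms both).  Plastic AMPA synapses
carry Tsodyks-Markram short-term depression: each presynaptic spike
consumes a fraction U = 0.25 of a resource x that recovers with
τ_rec = 500 ms; static synapses (pyramidal→basket, basket→pyramidal,
DBC→pyramidal) are not depressing.  The conductance increment of a plastic
synapse is `g_gain · max(w, 0) · U · x` — negative learned weights are
clipped at the conductance mapping, which enforces Dale's principle
mechanically (and is rarely active: the architecture is designed so the
relevant learned weights converge positive).

## Plasticity

Spike-based BCPNN.  Pre- and postsynaptic trains are low-pass filtered
into Z traces (τ_z = 5 ms; a spike contributes a rectangular pulse of
height 1/(f_max·t_spike) for t_spike, i.e. ~1/(f_max·τ_z) per spike with
the default t_spike = dt), which feed probability traces

    τ_p dP_i/dt = κ (Z_i − P_i),  τ_p dP_ij/dt = κ (Z_ij − P_ij),
    Z_ij := Z_i · Z_j,

and the weight and bias are the log-odds `w = log(P_ij/(P_i P_j))`,
`β_j = log(P_j)`.  κ = 1 throughout training (κ = 0 freezes learning
exactly).  The coactivation trace is the product of the two Z traces — the
delayed-reward eligibility stage of the rule family is bypassed, as no
reward signal exists in this protocol.  Each synapse's *pre*-side trace is
driven by the conduction-delay-shifted spike train (per delay class:
1.5 ms within an HC, 4.5 ms between), i.e. by the spikes as the synapse
sees them; post-side traces use emission times.  Weights are read with
their current value at each delayed spike arrival.  β is computed and
recorded but injects no current by default (`beta_gain = 0`).

Constants not fixed by the rule itself: f_max = 20 Hz, ε = 0.026 (the
probability floor), τ_p = 2000 ms.  These are the calibrated normalisation
(see Calibration).  Traces initialise at the ε floor with P_ij = ε², a
fixed point of the spike-free dynamics at which w = 0.

A statistical note: at low rates the coactivation trace is shot noise (at
10 Hz roughly one Z_i·Z_j coincidence per second enters a 2 s memory), so
the *instantaneous* log-odds weight of a single silent pair fluctuates
with a heavy left tail even though its expectation is zero.  The
independence null is therefore asserted on the weight implied by long-run
average P traces over an ensemble of pairs, which is the consistent
estimator; network-level snapshots average over hundreds of connections
and show the same null directly (initial weight means ≈ 0).

## Network and protocol

Populations: 30 pyramidal cells per MC (4 MCs), 8 basket cells per HC, and
exactly one DBC per MC, mirroring the anatomical one-DBC-per-minicolumn
estimate.  Wiring is Bernoulli per ordered pair (no autapses/multapses),
reproducible from the spec seed: plastic pyr→pyr recurrently within each
MC and between coactive MCs across HCs at p = 0.2; plastic pyr→DBC from
each MC onto the DBCs of its *competing* MCs at p = 0.2; static
pyr→basket and basket→pyr within each HC at p = 0.7; and each DBC
inhibits every pyramidal cell of its own MC.  No pyr→pyr connections
exist between competing MCs.  Delays: 1.5 ms within, 4.5 ms between HCs.

The training protocol (total 4.5 s): zero-mean Poisson noise throughout;
STIM0 at 1000–2000 ms drives the pyramids of MC0/MC2 *and the DBCs of
MC1/MC3*; STIM1 at 3000–4000 ms drives the complementary set.  Co-driving
each stimulus with the competing columns' DBCs is the key design feature —
pyramids and those DBCs then co-fire, so BCPNN learns positive pyr→DBC
weights that later deliver inhibition disynaptically.  Weight snapshots:
after the 1 s noise-only initialisation (IWD) and at 4.5 s (LWD).

The noise is realised as two independent Poisson conductance sources per
neuron (one AMPA-like, one GABA-like) with the inhibitory amplitude scaled
by the driving-force ratio at −70 mV so the mean injected current is ≈ 0
there.  Per-class amplitude scales (pyr 1.0, basket 0.7, DBC 0.25) reflect
that background bombardment scales with cell size and synapse count; the
DBC's sustained inter-stimulus spiking (~20 Hz here, vs ~45 Hz when
stimulated) is maintained by a 70 pA tonic depolarizing drive standing in
for unmodelled background excitation of these high-input-resistance cells.

## Calibration

The model's unprinted amplitudes (stimulus and noise rates/weights, static
synaptic weights, BCPNN normalisation) were calibrated once, jointly,
against the architecture's reference operating points — stimulated DBC
rate inside 43 ± 13 Hz, learned weight means near 1.7 (recurrent within
MC0), 1.3 (associative MC0→MC2) and 0.5 (MC0→DBC of MC1), initial means
near 0, and a ~220 pA peak of trial-averaged GABA input current onto MC0
pyramids during the competing stimulus — and then frozen in
`dbcnet/params.py`.  Two mechanisms position the weight means:

* The recurrent-vs-associative gap is *synchrony*, not rate: both
  projections see identical rate envelopes, but pyramids of one MC share
  their basket feedback loop, which groups their spikes at the few-ms
  timescale of τ_z (measured coincidence ratio ~1.4 within an MC vs ~1.1
  across HCs).  The product coactivation trace rewards that surplus,
  separating the two means by ~0.35 log units.
* The pyr→DBC mean (~0.5, versus ~1.7 for recurrent) is diluted by the
  DBC's sustained baseline firing, which inflates P_j outside the
  stimulation window.

## Recording conventions

Spike times are step-end times of threshold crossings.  `I_GABA` is the
current through network GABA synapses only (basket and DBC output),
negative (hyperpolarizing) whenever V > E_GABA; the noise channel is
excluded, matching the near-zero pre/post-stimulus level of the inhibition
profile.  `I_AMPA` includes stimulus events.  The inhibition profile
averages over MC0 pyramids, then over independent-seed trials, in 10 ms
bins; its peak is the maximum bin magnitude in the 3000–4000 ms window.
The shipped analysis uses 20 trials (the deskscale reduction of the
100-trial original); at 20 trials the across-batch spread of the peak is
roughly ±10 pA.

## What the simulation does and does not show

All inputs are synthetic (Poisson); there is no recorded data in the loop.
Passing tests demonstrate the *mechanism* — learned disynaptic inhibition
with Dale-compliant weights reproducing the reference weight distributions
and inhibition profile under the shipped calibration — not a fit to any
particular biological recording.  Known idealisations: one-compartment
cells (the DBC "horse-tail" axon is represented only by its connectivity
rule); single-exponential synapses without NMDA or facilitation; pyramidal
baseline activity under noise alone is near-silent in this calibration
(sparse, < 0.1 Hz) rather than visibly irregular; the pyr→DBC learned
distribution keeps a small negative tail (< 10 % of connections, clipped
to zero conductance at delivery); and the κ = 1, two-pattern protocol
leaves long-term retention/forgetting (τ_p ≫ protocol length) unexplored.

## Numerical choices

dt = 0.1 ms; delays must be integer multiples of dt (15 and 45 steps).
Update order per step: conductance decay and depression recovery → delayed
spike delivery (depression jump, conductance increment at the current
weight) → trace updates → stimulus/noise injection → current summation and
recording → membrane update, spike detection/reset, enqueue.  Separate
named random streams drive wiring, each stimulus, and the noise, so trials
with different seeds are fully independent while a fixed seed is
bit-reproducible.  Non-finite membrane states abort the run naming the
first offending neuron and time.
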