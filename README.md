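# dbcnet

A spiking-network model of a cortical columnar attractor memory in which
**double bouquet cells (DBCs)** carry the learned inhibition between
competing functional columns — so that Hebbian-Bayesian learning never has
to assign a negative weight to an excitatory synapse, and the circuit
respects Dale's principle.

The package is for computational neuroscientists who want a compact,
dependency-light (NumPy/SciPy/pandas) re-implementation of this
microcircuit: AdEx neurons, conductance AMPA/GABA synapses with
Tsodyks-Markram short-term depression, spike-based BCPNN plasticity, the
two-hypercolumn network with basket-cell winner-take-all pools and one DBC
per minicolumn, the two-stimulus training protocol, and the analysis that
turns recordings into weight distributions, firing rates and inhibitory
current profiles.

## Model core

Neurons follow the adaptive exponential integrate-and-fire equations

    C_m dV/dt = -g_L (V - E_L) + g_L Δ_T e^{(V - V_t)/Δ_T} - I_w + I_ext + I_syn
    dI_w/dt   = -I_w / τ_w,   I_w ← I_w + b per spike,

synaptic currents are conductance-based, `I_syn = -Σ g(t) (V - E_rev)`,
with short-term depression `dx/dt = (1-x)/τ_rec - U·x·Σδ(t-t_sp)` on
plastic synapses, and excitatory weights develop under the BCPNN rule:
spike trains are filtered into fast Z traces (τ_z = 5 ms) and slow
probability traces P_i, P_j, P_ij (τ_p = 2 s, gated by κ), giving

    w_ij = log( P_ij / (P_i P_j) ),    β_j = log P_j .

Pyramidal cells of one minicolumn excite the DBCs of the *competing*
minicolumns (plastic, 20 % connectivity); each DBC inhibits every pyramid
of its own minicolumn; basket cells provide winner-take-all feedback
within each hypercolumn.  Training two competing patterns leaves positive
recurrent/associative pyr→pyr weights and positive pyr→DBC weights —
inhibition between rivals is purely disynaptic.

## Worked example

`examples/` holds one short script per capability.  Training and readout
(`python examples/04_train_and_readout.py`, 3 trials, ~20 s) prints:

    weight-distribution means (IWD at 1 s -> LWD at 4.5 s):
      pyr MC0 -> pyr MC0 (recurrent)     +0.000 -> +1.675
      pyr MC0 -> pyr MC2 (associative)   +0.000 -> +1.379
      pyr MC0 -> DBC MC1 (competing)     +0.000 -> +0.259
      pyr MC0 -> DBC MC3 (competing)     -0.000 -> +0.527

    stimulated DBC rate (3-4 s):   51.0 Hz
    peak |I_GABA| onto MC0 pyr:    273 pA (during the competing stimulus)
    |I_GABA| before/after:         22 / 31 pA (near zero)
    Dale violations:               0

Read: after one second of zero-mean noise the plastic weights are still at
their independence null (≈ 0).  Training stimulus STIM0 (1–2 s) co-drives
the pyramids of MC0/MC2 with the DBCs of MC1/MC3, STIM1 (3–4 s) the
complement.  Afterwards the recurrent weights within a minicolumn are
strongest (≈ 1.7), the associative weights linking coactive minicolumns
across hypercolumns somewhat weaker (≈ 1.3–1.4), and the pyr→DBC weights
small but positive (≈ 0.5, noisy at 3 trials since each minicolumn has a
single DBC; at 20 trials the two pyr→DBC means settle near 0.46) — yet,
because DBCs have very high input resistance and contact every local
pyramid, they deliver inhibition comparable to the basket pathway: during
the competing stimulus the GABA input current onto MC0 pyramids peaks
near 220 pA (216 pA at 20 trials) and returns to baseline outside it.

Other entry points: `examples/01_dbc_electrophysiology.py` (the DBC cell
model: 658 MΩ input resistance, ≈ 43 Hz under a 77 pA step),
`examples/02_bcpnn_rule.py` (the learning rule on controlled spike
trains), `examples/03_network_and_protocol.py` (wiring audit and training
schedule).  The same functionality is available from the shell:

    dbcnet characterize-neuron --cell dbc
    dbcnet simulate --seed 7 --out out/
    dbcnet analyze --recordings out/ --projection "pyr_mc0->pyr_mc0" --snapshot 4500
    dbcnet reproduce --trials 20 --seed 1 --out summary.json

Every experiment is driven by one declarative YAML configuration
(`dbcnet.load_config`); an empty file is the complete default experiment,
and all defaults live in `dbcnet/params.py`.

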