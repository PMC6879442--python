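"""Train the microcircuit and read out what it learned.

Runs a few independent trials of the default 4.5 s protocol (zero-mean
noise throughout; STIM0 at 1-2 s, STIM1 at 3-4 s), then prints the initial
and learned weight-distribution means, the stimulated DBC firing rate, and
the trial-averaged inhibitory current onto MC0 pyramids.  With more trials
(20 in the full reproduction) the numbers tighten around the reference
operating points: recurrent ~1.7, associative ~1.3, pyr->DBC ~0.5,
inhibition peak ~220 pA.
"""

from dbcnet.workflows import reproduce

summary = reproduce(n_trials=3, seed=0, progress=True)

print("\nweight-distribution means (IWD at 1 s -> LWD at 4.5 s):")
labels = {
    "recurrent_mc0": "pyr MC0 -> pyr MC0 (recurrent)",
    "associative_mc0_mc2": "pyr MC0 -> pyr MC2 (associative)",
    "pyr_mc0_dbc_mc1": "pyr MC0 -> DBC MC1 (competing)",
    "pyr_mc0_dbc_mc3": "pyr MC0 -> DBC MC3 (competing)",
}
for key, label in labels.items():
    print(f"  {label:34s} {summary['iwd_mean'][key]:+.3f} -> "
          f"{summary['lwd_mean'][key]:+.3f}")

print(f"\nstimulated DBC rate (3-4 s):   {summary['dbc_rate_stim_hz']:.1f} Hz")
print(f"peak |I_GABA| onto MC0 pyr:    {summary['i_gaba_peak_pa']:.0f} pA "
      f"(during the competing stimulus)")
print(f"|I_GABA| before/after:         {summary['i_gaba_pre_window_pa']:.0f} / "
      f"{summary['i_gaba_post_window_pa']:.0f} pA (near zero)")
print(f"Dale violations:               {len(summary['dale_violations'])}")
print("\nCompetition is purely disynaptic: pyramids excite the competing "
      "columns' DBCs (learned, positive weights) and the local baskets, "
      "which inhibit the losing pyramids.")
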