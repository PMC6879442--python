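"""Characterise the double bouquet cell model.

Builds the DBC AdEx parameter set and measures its passive and active
electrophysiology: input resistance from a small hyperpolarizing step,
membrane time constant, rheobase, and the f-I curve.
"""

import numpy as np

from dbcnet import fI_curve, measure_input_resistance
from dbcnet.params import DBC, DBC_STRONG_STEP_PA

r_in = measure_input_resistance(DBC, i_step=-5.0)
print(f"input resistance:        {r_in:.1f} MOhm   (reported ~660 MOhm)")
print(f"membrane time constant:  {DBC.tau_m:.2f} ms     (reported 17.1 +/- 7.7 ms)")
print(f"rheobase:                {DBC.rheobase:.1f} pA")

currents = np.arange(40.0, 130.0, 10.0)
rates = fI_curve(DBC, currents, duration=2000.0)
print("\n  I (pA)   rate (Hz)")
for i, r in zip(currents, rates):
    print(f"  {i:6.0f}   {r:8.1f}")

strong = fI_curve(DBC, [DBC_STRONG_STEP_PA], duration=2000.0)[0]
print(f"\nrate at the {DBC_STRONG_STEP_PA:.0f} pA 'strong stimulation' step: "
      f"{strong:.1f} Hz (reported band 43 +/- 13 Hz)")
print("Below ~47 pA the cell is silent; above, it fires tonically with a "
      "mild adaptation-driven rate decline (b = 3 pA).")
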