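"""Build the two-hypercolumn network and inspect its wiring and protocol.

Realizes the default topology (2 HCs x 2 MCs, one DBC per MC, basket-cell
winner-take-all pools), audits Dale's principle, and prints the training
schedule with its target populations.
"""

from dbcnet.network import NetworkSpec, build, competing_mcs, dale_violations
from dbcnet.stimulation import default_protocol

spec = NetworkSpec(rng_seed=42)
net = build(spec)

print(f"{net.n_neurons} neurons: "
      f"{sum(len(net.populations[f'pyr_mc{m}']) for m in range(4))} pyramidal, "
      f"{sum(len(net.populations[f'basket_hc{h}']) for h in range(2))} basket, "
      f"{sum(len(net.populations[f'dbc_mc{m}']) for m in range(4))} DBC")
for mc in range(4):
    print(f"  MC{mc} competes with {competing_mcs(spec, mc)}")

print("\nprojections (name, connections, delay, receptor, plastic):")
for p in net.projections:
    print(f"  {p.name:26s} {p.n_connections:4d}  {p.delay} ms  "
          f"{p.receptor:4s}  {'plastic' if p.plastic else 'static'}")
print(f"\nDale violations: {dale_violations(net) or 'none'}")

proto = default_protocol(spec)
print("\ntraining schedule:")
for s in proto.stimuli:
    targets = ", ".join(f"{cls}@MC{mc}" for cls, mc in s.targets)
    print(f"  {s.label}: {s.window[0]:.0f}-{s.window[1]:.0f} ms, "
          f"{s.rate:.0f} Hz x {s.weight} nS -> {targets}")
print("Each stimulus co-drives the DBCs of the *competing* columns, so the "
      "plastic pyr->DBC weights learn positive values.")
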