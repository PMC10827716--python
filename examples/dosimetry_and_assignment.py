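"""Electrode dosimetry and stratified group assignment.

Converts the four standard current densities to absolute currents through
the 4-mm epicranial electrode, then assigns a small cohort to arms by
sequential minimization on their post-stroke severity scores.
"""

from strokequant import StimulationProtocol, printed_contact_area, stratified_assign

print("electrode: 4 mm inner diameter ->",
      f"{printed_contact_area(4.0)} mm^2 contact area (two-decimal print)")
for density in (0.0, 0.8, 31.8, 47.8):
    p = StimulationProtocol(current_density=density)
    print(f"  {density:5.1f} A/m^2  ->  {p.current_uA:7.1f} uA "
          f"for {p.duration_min:.0f} min")

# post-stroke mNSS totals in arrival order; the assigner keeps arm sizes
# within one and arm-mean scores as close as possible
scores = [8, 6, 9, 7, 8, 5, 10, 7, 6, 9, 8, 7]
arms = stratified_assign(scores, n_arms=4, seed=1)
print("\nanimal scores:", scores)
print("assigned arms:", arms)
for a in range(4):
    members = [s for s, l in zip(scores, arms) if l == a]
    print(f"  arm {a}: n={len(members)}, mean mNSS={sum(members)/len(members):.2f}")
print("-> arm means stay comparable although animals arrived in a fixed order")
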