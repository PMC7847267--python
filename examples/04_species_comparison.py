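"""Cross-species disc stress: human, giraffe, australopith.

Compares everyday loading conditions: an erect human (phi=90 deg), a
roaming giraffe holding its neck at the neutral 60 deg, and an
A. afarensis trunk at 60 deg. The sensitivity multiplier
S = M*L_com/(A_disc*R_pull) governs how fast each species' disc stress
climbs on forward flexion.
"""

from spinebase import (
    australopith_preset,
    compare_species,
    giraffe_preset,
    human_preset,
    sensitivity_multiplier,
)

human = human_preset().params
giraffe = giraffe_preset().params
afarensis = australopith_preset("afarensis").params

comp = compare_species([human, giraffe, afarensis], [90.0, 60.0, 60.0])
print(comp.table.to_string(float_format=lambda x: f"{x:.3g}"))
print("\npairwise stress ratios (row / column):")
print(comp.pairwise.to_string(float_format=lambda x: f"{x:.3g}"))

print("\nsensitivity multiplier S = M*L/(A*R), kg/m^2:")
for p in (human, giraffe, afarensis):
    print(f"  {p.label:6s} {sensitivity_multiplier(p):10.0f}")

print(
    "\nAn erect human carries about a third of a roaming giraffe's disc\n"
    "stress; the afarensis trunk at the same 60 deg bend already matches\n"
    "the giraffe's everyday maximum. Both hominin levels have a steeper S\n"
    "than the giraffe's neck base: flexion is comparatively expensive for\n"
    "the lumbar disc."
)
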