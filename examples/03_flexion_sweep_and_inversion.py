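"""Stress versus flexion angle, its maximum, and inverse queries.

Sweeps the human preset over the full 0-90 deg inclination range, locates
the angle of maximum stress analytically (atan(R_pull/L_com)), and inverts
the model: at which angle does the disc see a target stress or the joint a
target torque?
"""

from spinebase import (
    angle_for_stress,
    angle_for_torque,
    angle_of_max_stress,
    compressive_stress,
    human_preset,
    stress_sweep,
)

params = human_preset().params

table = stress_sweep(params, step=15.0).to_dataframe()
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

phi_star = angle_of_max_stress(params)
print(f"\nmaximum stress {compressive_stress(params, phi_star) / 1e6:.3f} MPa "
      f"at phi* = {phi_star:.1f} deg (almost fully flexed)")

phi_g = angle_for_stress(params, 1.4e6, "erect")
print(f"the giraffe's everyday maximum of 1.4 MPa is reached at phi = {phi_g:.1f} deg,"
      f"\n  i.e. flexing the trunk forward by {90 - phi_g:.0f} deg")

phi_t = angle_for_torque(params, 30.0)
print(f"a 30 N·m joint torque occurs at phi = {phi_t:.1f} deg "
      "(13 deg of forward bend)")
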