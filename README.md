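# spinebase

Static predictions of the compressive load on the intervertebral disc (IVD)
at the base of an erect spine segment — the lumbar L4/L5 disc under the
human (or australopith) head–arms–trunk, and the cervical C7/T1 disc under a
giraffe's neck — as a function of the segment's inclination angle, together
with the conical-frustum morphometry used to derive segment masses and
centres of mass.

The package is aimed at comparative biomechanists and anyone teaching or
exploring spine loading: it turns four anatomical numbers per species into
the full load state at any posture, sweeps, inverse queries ("at which angle
does the disc see 1.4 MPa?") and cross-species comparisons, from Python or
a small CLI.

## The model

A rigid segment of mass *M* (human HAT ≈ 51 kg, giraffe head–neck assembly
≈ 147 kg) is suspended at a single joint in the base IVD. Its CoM lies a
distance *L*<sub>CoM</sub> from the joint along the segment axis. One lumped
structure (muscles plus ligaments; in the giraffe chiefly the nuchal
ligament) pulls along the segment axis past the joint with lever arm
*R*<sub>pull</sub> and balances the weight torque. With the inclination
angle φ measured from horizontal (90° = fully erect, 0° = fully flexed):

- torque τ = *M g L*<sub>CoM</sub> cos φ
- pulling force *F*<sub>pull</sub> = τ / *R*<sub>pull</sub>
- compressive force *F*<sub>∥</sub> = *F*<sub>pull</sub> + *M g* sin φ
- shear force = *M g* cos φ
- compressive stress *P* = *F*<sub>∥</sub> / *A*<sub>disc</sub>
- intradiscal pressure ≈ 1.4 × *P* (empirical in-vitro conversion)

The stress peaks at φ\* = atan(*R*<sub>pull</sub>/*L*<sub>CoM</sub>) and the
species-specific multiplier *S* = *M L*<sub>CoM</sub> /
(*A*<sub>disc</sub> *R*<sub>pull</sub>) sets how steeply stress grows with
forward flexion. Facet-joint forces and co-contraction are neglected, so
the predictions are a static minimum. Segment masses and CoM positions come
from closed-form elliptic/circular frustum morphometry (volume, CoM at
(h/4)(1+2α+3α²)/(1+α+α²)), verified against a numerical slicing oracle.

## Worked example

```python
from spinebase import human_preset, load_state

params = human_preset().params          # 51 kg, 0.265 m, 4.9 cm, 15 cm^2
for phi in (90.0, 60.0, 0.0):
    st = load_state(params, phi)
    print(f"phi={phi:5.1f}  stress={st.compressive_stress/1e6:.3f} MPa  "
          f"pressure={st.intradiscal_pressure/1e6:.3f} MPa")
```

prints

```
phi= 90.0  stress=0.334 MPa  pressure=0.467 MPa
phi= 60.0  stress=1.191 MPa  pressure=1.667 MPa
phi=  0.0  stress=1.804 MPa  pressure=2.525 MPa
```

Fully erect, the 51 kg trunk weight alone presses 0.334 MPa onto the 15 cm²
endplate, an intradiscal pressure of 0.47 MPa — the value measured in vivo
in standing subjects. Bending forward by 30° multiplies the stress ~3.6-fold
because the pulling structure must now balance a 66 N·m torque across a
4.9 cm lever; fully flexed, the pull reaches 2.7 kN. The `examples/`
directory holds one short script per capability (single postures, giraffe
frustum morphometry, sweeps and inversion, species comparison); the same
calculations are available from the shell, e.g.
`spinebase point --species human --angle 60` or
`spinebase sweep --species giraffe --step 1 --out sweep.csv`.

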