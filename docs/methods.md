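# Methods

## Model and assumptions

The package implements a deliberately reductionist statics model of the
spine base. A rigid body segment — the human head–arms–trunk (HAT) or the
giraffe head–neck assembly (HENE) — hangs from a single rotational joint
placed in the intervertebral disc (IVD) at the segment base (L4/L5 in
hominins, C7/T1 in giraffes). Exactly one lumped structure (the net effect
of all muscles and ligaments crossing the joint; in the giraffe dominated by
the nuchal ligament) pulls parallel to the segment's longitudinal axis with
a fixed perpendicular lever arm `R_pull` and supplies the whole
weight-compensating torque. Static force and torque equilibrium then give,
with `phi` the inclination from horizontal (90° fully erect, 0° fully
flexed):

```
tau      = M * g * L_com * cos(phi)          joint bending torque
F_pull   = tau / R_pull                      lumped pulling force
F_par    = F_pull + M * g * sin(phi)         axial compressive force on the IVD
F_shear  = M * g * cos(phi)                  transverse weight component
P        = F_par / A_disc                    compressive stress
p_ivd    = 1.4 * P                           intradiscal pressure estimate
```

Assumptions worth keeping in mind:

- The pulling force is axial, so it adds compression but no shear; the only
  shear is the transverse weight component. Facet-joint forces, the disc's
  own torque contribution, and antagonist co-contraction are all neglected.
  The predicted compression is therefore the *static minimum* demanded by
  equilibrium; any co-contraction raises the real load above it.
- The loaded surface is taken perpendicular to the segment axis at every
  angle, for every species, so stresses are directly comparable.
- The model is evaluated only on `phi` in [0°, 90°]; angles outside raise
  `AngleDomainError` rather than extrapolate, since the equilibrium
  reading (a suspended segment, tension-only pulling structure) does not
  carry over.

Because `P(phi)` is a single sinusoid `K*sin(phi + delta)`, it has one
interior maximum at `phi* = atan(R_pull / L_com)` (≈10.5° for the human
parameters) and is strictly monotonic on either side, which makes inverse
queries well-posed per branch. The pulling-induced part of the stress is
`g*S*cos(phi)` with the sensitivity multiplier `S = M*L_com/(A_disc*R_pull)`
(units kg/m²; `g` is kept out of `S` so the multiplier is a pure
anatomy/geometry number). Only the ordering of `S` across species and the
slope proportionality are used quantitatively.

## Parameters

| parameter | meaning | human (L4/L5) | giraffe (C7/T1) | A. afarensis (L4) |
|---|---|---|---|---|
| `mass` (kg) | suspended mass | 51 | 147 | 34 |
| `com_distance` (m) | CoM from joint | 0.265 | 0.80 | 0.265 |
| `pull_lever` (m) | lumped lever arm | 0.049 | 0.155 | 0.037 |
| `disc_area` (m²) | endplate ellipse | 15.0 cm² | 52.2 cm² | 10.6 cm² |
| `gravity` (m/s²) | g | 9.81 | 9.81 | 9.81 |
| `pressure_factor` | stress→pressure | 1.4 | 1.4 | 1.4 |

`g = 9.81 m/s²` reproduces the reference full-flexion values (2706 N,
132.6 N·m) exactly. The 1.4 stress-to-pressure factor stems from in-vitro
disc preparations and is kept per-parameter-set, so giraffe intradiscal
pressure is computable on request even though it is conventionally reported
only for hominins. A `boisei` variant carries the older, much smaller
endplate areas (3.6–5.2 cm², default 5.2 cm²) with the same 34 kg trunk and
3.7 cm lever.

## Frustum morphometry

Body parts are homogeneous conical frustums. An elliptic frustum (base
half-axes `a` sagittal, `b` frontal) shares volume and axial CoM with the
circular frustum of equivalent radius `r = sqrt(a*b)`:

```
V     = (pi/3) * h * r^2 * (1 + alpha + alpha^2)
l_com = (h/4) * (1 + 2*alpha + 3*alpha^2) / (1 + alpha + alpha^2)
```

with `alpha` the top/base ratio; `alpha = 1` is the cylinder (l = h/2),
`alpha = 0` the accepted cone limit (l = h/4), and `l_com` increases
strictly with `alpha` in between. Multi-part assembly is a mass-weighted
mean of part CoM positions on the proximal axis. Two mounting semantics
exist: axial stacking (the distal part continues the axis; its CoM sits at
proximal length + its own offset) and transverse mounting (a head carried
on a neck tip; the axial offset of its CoM beyond the neck is half the
head's sagittal diameter at the head-CoM height, linearly interpolated
along the taper). The giraffe assembly uses the transverse rule; the
associativity and composite-integral properties are stated for axial
chains.

### The reference giraffe

The bundled giraffe morphometry describes an adult female of ~800 kg and
1.55 m neck length. Published sources give only derived quantities for this
animal (segment masses 120 and 27 kg, CoM offsets 0.60 and 0.215 m, head
height 0.34 m, HENE 147 kg at 0.80 m); the frustum base/top dimensions in
`presets.py` (neck base 0.294 m × 0.588 m, width:depth 2 within the
documented 2–3 range, `alpha = 0.478`; head base diameter 0.34 m,
`alpha = 0.315`, length 0.63 m) were calibrated once so that the closed
forms reproduce every one of those derived values with water-like density
(1000 kg/m³, the package default). The same applies to the C7/T1 endplate
ellipse (9.5 cm × 7.0 cm = 52.2 cm²), which was fixed by inverting
`P = F/A` at the reported everyday stress of 0.95 MPa at 60°; the preset
then also reproduces 1.37 ≈ 1.4 MPa at 30° without further adjustment. These
dimensions are *representative reconstructions*, not measurements: tests
passing on them show internal consistency of the morphometry chain, not
fidelity to any individual animal.

## Numerical choices

- **Root finding** (`angle_for_stress`): bracketed Brent iteration on the
  chosen monotonic branch (`erect` = [phi*, 90°], the default and the branch
  on which all everyday postures lie; `flexed` = [0°, phi*]), with
  `xtol = 1e-12` degrees, so the returned angle reproduces the target stress
  to ~1e-9 relative. Targets within 1e-9 (relative) of a bracket endpoint
  are clamped to it to absorb float fuzz such as `cos(90°) ≈ 6e-17`; truly
  unattainable targets raise `TargetOutOfRangeError` naming the attainable
  range. Torque inversion is closed-form (`acos`).
- **Sweeps**: inclusive uniform grids over [0°, 90°]; if the step does not
  divide 90 the final interval is shortened so both endpoints are always
  present. Sweep rows are pointwise `load_state` calls, bit-identical to
  single-angle evaluation.
- **Slicing oracle**: trapezoidal integration of the cross-section area
  profile with ≥100 slices, `O(n^-2)` convergent; the suite checks 1000
  random frustums at 20 000 slices against the closed forms at 1e-6
  relative.
- **Printed-value tolerance**: reference predictions are quoted to 2–3
  figures, so reproduction tests use a 2% relative band. Two values sit at
  the edge of their rounding: the flexion factor recomputes to 3.570
  (printed 3.5, 2.003% away — the one test uses 2.1% for this ratio) and
  the stress maximum recomputes to 1.834 MPa at 10.5° (printed 1.85 at
  ~10°). These are documented rather than forced.
- One reported sensitivity case — 0.93–1.31 MPa attributed to a fully erect
  posture with a 2.6 cm lever — cannot be reproduced by this model, since
  at 90° the pulling force vanishes and the lever arm drops out of the
  equations; it is deliberately not targeted.

## Parameter files and units

Presets serialise to YAML in which every physical key carries an explicit
unit suffix (`mass_kg`, `com_distance_m`/`_cm`, `pull_lever_m`/`_cm`,
`disc_area_m2`/`_cm2`, `gravity_m_s2`, dimensionless `pressure_factor`;
frustum blocks analogous). Values convert to SI on read; unknown fields,
repeated fields, missing units and non-positive values are rejected with
the offending field named. Internally everything is SI; the CLI formats
stresses in MPa to 3 significant figures and forces in N to one decimal.

## Limitations

Rigid single segment, one degree of freedom, one lumped pulling structure
with a posture-independent lever arm; homogeneous densities; no facet
joints, no co-contraction, no ligament elasticity or rest lengths, no
dynamics. The model predicts accumulative compressive load well precisely
because the IVD is the only compressed element in flexion, but it cannot
resolve load sharing among individual structures — for that a
structure-resolved spine model is required.
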