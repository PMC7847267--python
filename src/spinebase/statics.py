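"""Static equilibrium of a spine segment suspended at its base joint.

The model has a single rotational degree of freedom: a rigid segment of mass
``M`` (the human head–arms–trunk, HAT, or the giraffe head–neck assembly,
HENE) is suspended at the intervertebral disc (IVD) at its base — L4/L5 in
hominins, C7/T1 in giraffes. A single lumped structure (muscles plus
ligaments, e.g. the nuchal ligament) pulls along the segment's longitudinal
axis past the joint with lever arm ``R_pull`` and compensates the bending
torque the segment weight exerts about the joint.

With the inclination angle ``phi`` measured from horizontal (90 deg = fully
erect, 0 deg = fully forward flexed) and ``L_com`` the CoM distance from the
joint:

    torque       tau     = M * g * L_com * cos(phi)
    pulling      F_pull  = tau / R_pull
    compressive  F_par   = F_pull + M * g * sin(phi)
    shear        F_shear = M * g * cos(phi)
    stress       P       = F_par / A_disc
    pressure     p_ivd   = pressure_factor * P      (empirically ~1.4)

Facet-joint forces and muscle co-contraction are neglected: the predicted
compressive load is the static minimum demanded by equilibrium. The model is
evaluated on phi in [0, 90] degrees only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import AngleDomainError, InvalidParameterError

__all__ = [
    "SpineBaseParams",
    "LoadState",
    "bending_torque",
    "pulling_force",
    "compressive_force",
    "shear_force",
    "compressive_stress",
    "weight_stress",
    "intradiscal_pressure",
    "sensitivity_multiplier",
    "load_state",
]

STANDARD_GRAVITY = 9.81
"""Gravitational acceleration, m/s^2."""

STRESS_TO_PRESSURE = 1.4
"""Empirical conversion from external compressive stress on the disc to
intradiscal (nucleus) pressure, determined in vitro."""


@dataclass(frozen=True)
class SpineBaseParams:
    """The four-parameter mechanical description of one species' spine base.

    Attributes
    ----------
    mass : float
        Suspended mass above the base joint, kg (M_HAT or M_HENE).
    com_distance : float
        Distance of the suspended mass's CoM from the base joint along the
        segment axis, m.
    pull_lever : float
        Lever arm R_pull of the lumped torque-compensating pulling structure
        about the joint, m.
    disc_area : float
        Loaded endplate/IVD cross-sectional area, m^2.
    gravity : float
        Gravitational acceleration, m/s^2 (default 9.81).
    pressure_factor : float
        Dimensionless compressive-stress -> intradiscal-pressure multiplier
        (default 1.4).
    label : str
        Species/spinal-level identifier, e.g. "L4/L5" or "C7/T1".
    """

    mass: float
    com_distance: float
    pull_lever: float
    disc_area: float
    gravity: float = STANDARD_GRAVITY
    pressure_factor: float = STRESS_TO_PRESSURE
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("mass", "com_distance", "pull_lever", "disc_area",
                     "gravity", "pressure_factor"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class LoadState:
    """All mechanical outputs of the model at one inclination angle.

    Forces in N, torque in N·m, stresses/pressure in Pa; ``phi_deg`` in
    degrees with 90 = fully erect.
    """

    phi_deg: float
    bending_torque: float
    pulling_force: float
    compressive_force: float
    shear_force: float
    compressive_stress: float
    weight_stress: float
    intradiscal_pressure: float


def _phi_rad(phi_deg: float) -> float:
    if not 0.0 <= phi_deg <= 90.0:
        raise AngleDomainError(
            f"inclination angle {phi_deg} deg outside the model's validity "
            "range [0, 90] (90 = fully erect, 0 = fully flexed)"
        )
    return math.radians(phi_deg)


def bending_torque(p: SpineBaseParams, phi_deg: float) -> float:
    """Weight-induced bending torque about the base joint: M·g·L_com·cos(phi), N·m."""
    return p.mass * p.gravity * p.com_distance * math.cos(_phi_rad(phi_deg))


def pulling_force(p: SpineBaseParams, phi_deg: float) -> float:
    """Force in the lumped pulling structure that balances the torque: tau/R_pull, N."""
    return bending_torque(p, phi_deg) / p.pull_lever


def compressive_force(p: SpineBaseParams, phi_deg: float) -> float:
    """Axial compressive load on the base IVD: F_pull + M·g·sin(phi), N."""
    return pulling_force(p, phi_deg) + p.mass * p.gravity * math.sin(_phi_rad(phi_deg))


def shear_force(p: SpineBaseParams, phi_deg: float) -> float:
    """Transverse component of the segment weight at the joint: M·g·cos(phi), N.

    The pulling structure is modelled as axial, so only the weight
    contributes shear: zero fully erect, M·g in horizontal posture.
    """
    return p.mass * p.gravity * math.cos(_phi_rad(phi_deg))


def compressive_stress(p: SpineBaseParams, phi_deg: float) -> float:
    """Compressive stress on the base IVD: F_par / A_disc, Pa."""
    return compressive_force(p, phi_deg) / p.disc_area


def weight_stress(p: SpineBaseParams, phi_deg: float) -> float:
    """Directly weight-induced part of the compressive stress: M·g·sin(phi)/A_disc, Pa."""
    return p.mass * p.gravity * math.sin(_phi_rad(phi_deg)) / p.disc_area


def intradiscal_pressure(p: SpineBaseParams, phi_deg: float) -> float:
    """Predicted intradiscal pressure: pressure_factor × compressive stress, Pa."""
    return p.pressure_factor * compressive_stress(p, phi_deg)


def sensitivity_multiplier(p: SpineBaseParams) -> float:
    """Species-specific multiplier S = M·L_com / (A_disc·R_pull), kg/m^2.

    The pulling-force-induced stress is ``g * S * cos(phi)``, so S (times g)
    is the slope of that contribution against cos(phi); species with larger
    S see their disc stress rise faster on forward flexion.
    """
    return p.mass * p.com_distance / (p.disc_area * p.pull_lever)


def load_state(p: SpineBaseParams, phi_deg: float) -> LoadState:
    """Evaluate every load quantity of the model at one inclination angle."""
    tau = bending_torque(p, phi_deg)
    f_pull = tau / p.pull_lever
    f_comp = f_pull + p.mass * p.gravity * math.sin(math.radians(phi_deg))
    return LoadState(
        phi_deg=phi_deg,
        bending_torque=tau,
        pulling_force=f_pull,
        compressive_force=f_comp,
        shear_force=shear_force(p, phi_deg),
        compressive_stress=f_comp / p.disc_area,
        weight_stress=weight_stress(p, phi_deg),
        intradiscal_pressure=p.pressure_factor * f_comp / p.disc_area,
    )
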