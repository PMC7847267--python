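"""Frustum-based body-segment morphometry.

Body parts (a giraffe's neck, its head, or any roughly tapered limb segment)
are modelled as homogeneous conical frustums with an elliptic or circular
base. An elliptic frustum with base half-axes ``a`` (sagittal) and ``b``
(frontal) has the same base area, volume and centre-of-mass (CoM) position
along its longitudinal axis as a circular frustum of the *equivalent radius*
``r = sqrt(a*b)``, which is why all mass properties here reduce to the
circular closed forms:

    V      = (pi/3) * h * r^2 * (1 + alpha + alpha^2)
    l_CoM  = (h/4) * (1 + 2*alpha + 3*alpha^2) / (1 + alpha + alpha^2)

with ``alpha`` the top-to-base radius ratio (``alpha = 1`` is a cylinder,
``alpha = 0`` the cone limit) and ``h`` the frustum height. Multi-part
segments (e.g. neck + head) are assembled into a single mass and CoM by a
mass-weighted mean of the part CoM positions, all expressed along the
longitudinal axis of the proximal part with origin at its base joint.

A slicing quadrature oracle (`numeric_com_oracle`) provides an independent
check of the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "FrustumSpec",
    "BodySegment",
    "equivalent_radius",
    "frustum_volume",
    "frustum_com_offset",
    "segment_from_frustum",
    "assemble_inline_com",
    "numeric_com_oracle",
]


def equivalent_radius(a: float, b: float) -> float:
    """Radius of the circle with the same area as an ellipse of half-axes *a*, *b*.

    Parameters
    ----------
    a, b
        Sagittal and frontal half-axes in metres; both must be positive.

    Returns
    -------
    float
        ``sqrt(a * b)`` in metres, so that ``pi*a*b == pi*r**2``.
    """
    if a <= 0 or b <= 0:
        raise InvalidParameterError(f"half-axes must be positive, got a={a}, b={b}")
    return float(np.sqrt(a * b))


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(
            f"top-to-base ratio alpha must lie in [0, 1], got {alpha}"
        )


def frustum_volume(r: float, alpha: float, h: float) -> float:
    """Volume of a circular frustum of base radius *r*, top radius *alpha*·*r*, height *h*.

    ``alpha = 1`` recovers the cylinder ``pi*r**2*h``; ``alpha = 0`` the cone
    ``pi*r**2*h/3``.
    """
    if r <= 0 or h <= 0:
        raise InvalidParameterError(f"r and h must be positive, got r={r}, h={h}")
    _check_alpha(alpha)
    return float(np.pi / 3.0 * h * r * r * (1.0 + alpha + alpha * alpha))


def frustum_com_offset(h: float, alpha: float) -> float:
    """Centre-of-mass height above the base of a homogeneous frustum.

    ``l = (h/4) * (1 + 2*alpha + 3*alpha^2) / (1 + alpha + alpha^2)``, which is
    ``h/4`` for a cone (``alpha = 0``) and ``h/2`` for a cylinder
    (``alpha = 1``), and increases strictly with *alpha* in between.
    """
    if h <= 0:
        raise InvalidParameterError(f"height must be positive, got h={h}")
    _check_alpha(alpha)
    s = 1.0 + alpha + alpha * alpha
    return float(h / 4.0 * (1.0 + 2.0 * alpha + 3.0 * alpha * alpha) / s)


@dataclass(frozen=True)
class FrustumSpec:
    """Geometric and density description of one frustum-shaped body part.

    Attributes
    ----------
    sagittal_half_axis : float
        Base half-axis ``a`` in the sagittal plane, m.
    frontal_half_axis : float
        Base half-axis ``b`` in the frontal plane, m (equal to ``a`` for a
        circular part such as the head).
    top_to_base_ratio : float
        ``alpha`` in [0, 1]; the top cross-section is the base scaled by
        ``alpha`` (0 = cone limit, 1 = cylinder).
    height : float
        Frustum height ``h`` along the longitudinal axis, m.
    density : float
        Homogeneous body density, kg/m^3; default 1000 (water-like soft
        tissue).
    """

    sagittal_half_axis: float
    frontal_half_axis: float
    top_to_base_ratio: float
    height: float
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.sagittal_half_axis <= 0 or self.frontal_half_axis <= 0:
            raise InvalidParameterError("frustum half-axes must be positive")
        if self.height <= 0:
            raise InvalidParameterError("frustum height must be positive")
        if self.density <= 0:
            raise InvalidParameterError("density must be positive")
        _check_alpha(self.top_to_base_ratio)

    @property
    def equivalent_radius(self) -> float:
        return equivalent_radius(self.sagittal_half_axis, self.frontal_half_axis)

    @property
    def base_area(self) -> float:
        """Elliptic base area pi*a*b, m^2."""
        return float(np.pi * self.sagittal_half_axis * self.frontal_half_axis)

    @property
    def volume(self) -> float:
        return frustum_volume(self.equivalent_radius, self.top_to_base_ratio, self.height)

    @property
    def mass(self) -> float:
        return self.density * self.volume

    @property
    def com_offset(self) -> float:
        return frustum_com_offset(self.height, self.top_to_base_ratio)

    def sagittal_diameter_at(self, z: float) -> float:
        """Sagittal diameter of the cross-section at height *z* above the base.

        Linear taper: ``2*a*(1 - (1 - alpha)*z/h)``.
        """
        if not 0.0 <= z <= self.height:
            raise InvalidParameterError(
                f"z={z} outside the frustum height [0, {self.height}]"
            )
        taper = 1.0 - (1.0 - self.top_to_base_ratio) * z / self.height
        return 2.0 * self.sagittal_half_axis * taper


@dataclass(frozen=True)
class BodySegment:
    """Mass and CoM of a body part (or assembly) along its longitudinal axis.

    ``com_offset`` is measured from the segment base joint toward the head.
    ``depth_at_com`` is the sagittal (transverse) extent of the part at its
    CoM height; it is only consulted when the part is mounted transversely on
    top of a proximal part (the giraffe-head case).
    """

    mass: float
    com_offset: float
    length: float
    depth_at_com: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InvalidParameterError("segment mass must be positive")
        if self.length <= 0:
            raise InvalidParameterError("segment length must be positive")
        if not 0.0 <= self.com_offset <= self.length:
            raise InvalidParameterError(
                f"com_offset {self.com_offset} outside [0, {self.length}]"
            )
        if self.depth_at_com < 0:
            raise InvalidParameterError("depth_at_com must be non-negative")


def segment_from_frustum(spec: FrustumSpec) -> BodySegment:
    """Mass properties of one frustum part: M = rho*V, CoM from the closed form.

    ``depth_at_com`` is the sagittal diameter linearly interpolated at the CoM
    height, which is what the transverse-mounting rule of
    `assemble_inline_com` needs.
    """
    l_com = spec.com_offset
    return BodySegment(
        mass=spec.mass,
        com_offset=l_com,
        length=spec.height,
        depth_at_com=spec.sagittal_diameter_at(l_com),
    )


def assemble_inline_com(
    proximal: BodySegment, distal: BodySegment, *, transverse: bool = False
) -> BodySegment:
    """Combine a distal part mounted at the top of a proximal part.

    The combined mass is the sum; the combined CoM is the mass-weighted mean
    of the part CoM positions expressed from the proximal base.

    With ``transverse=False`` (default) the distal part continues along the
    proximal axis, so its CoM sits at ``proximal.length + distal.com_offset``.
    With ``transverse=True`` the distal part's own axis is roughly
    perpendicular to the proximal axis (a head carried on top of a neck): the
    axial offset of its CoM beyond the proximal tip is then half its depth at
    the CoM position, ``distal.depth_at_com / 2``.
    """
    if transverse:
        distal_pos = proximal.length + distal.depth_at_com / 2.0
        total_len = proximal.length + distal.depth_at_com
    else:
        distal_pos = proximal.length + distal.com_offset
        total_len = proximal.length + distal.length
    m = proximal.mass + distal.mass
    com = (proximal.mass * proximal.com_offset + distal.mass * distal_pos) / m
    return BodySegment(mass=m, com_offset=com, length=total_len, depth_at_com=0.0)


def numeric_com_oracle(spec: FrustumSpec, n_slices: int = 10_000) -> tuple[float, float]:
    """Mass and CoM of a frustum by trapezoidal slicing, independent of the closed forms.

    Integrates the elliptic cross-section area ``pi * a(z) * b(z)`` over the
    height with *n_slices* uniform intervals (at least 100). Converges to the
    closed-form volume and CoM as ``O(n_slices**-2)``.
    """
    if n_slices < 100:
        raise InvalidParameterError("n_slices must be at least 100")
    z = np.linspace(0.0, spec.height, n_slices + 1)
    taper = 1.0 - (1.0 - spec.top_to_base_ratio) * z / spec.height
    area = np.pi * spec.sagittal_half_axis * spec.frontal_half_axis * taper**2
    vol = np.trapezoid(area, z)
    com = np.trapezoid(z * area, z) / vol
    return float(spec.density * vol), float(com)
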