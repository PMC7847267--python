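"""Species parameter presets and YAML parameter-file IO.

Three built-in parameter sets drive the spine-base load model:

* ``human``      — male, 1.75 m / 75 kg; head–arms–trunk (HAT) of 51 kg with
  its CoM 0.265 m above the L4/L5 disc, pulling lever 4.9 cm, elliptic
  endplate area 15 cm^2.
* ``giraffe``    — adult female, ~800 kg, neck length 1.55 m; head–neck
  assembly (HENE) of 147 kg, CoM 0.80 m from C7/T1, nuchal-ligament lever
  15.5 cm, endplate ellipse 9.5 cm x 7.0 cm. The HENE mass and CoM are
  re-derivable from the bundled frustum morphometry (see
  `derive_hene_segment`).
* australopiths — 1.63 m / 50 kg body (the largest specimen considered),
  hence HAT mass 34 kg with a human-like CoM distance 0.265 m and pulling
  lever 3.7 cm; the *afarensis* variant uses the L4 endplate 4.8 cm x 2.8 cm
  (10.6 cm^2), the *boisei* variant the older, much smaller endplate areas
  (3.6–5.2 cm^2, default 5.2 cm^2).

Parameter files are YAML with explicit unit suffixes on every physical key
(``mass_kg``, ``com_distance_m`` / ``_cm``, ``disc_area_m2`` / ``_cm2``, ...);
unknown fields and missing units are rejected, and all values are stored in
SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError, ParameterFileError
from .morphometry import (
    BodySegment,
    FrustumSpec,
    assemble_inline_com,
    segment_from_frustum,
)
from .statics import SpineBaseParams

__all__ = [
    "SpeciesPreset",
    "human_preset",
    "giraffe_preset",
    "australopith_preset",
    "ellipse_area",
    "derive_hene_segment",
    "read_params",
    "write_params",
]


def ellipse_area(width: float, depth: float) -> float:
    """Area of an ellipse with full *width* and *depth* as its diameters, m^2.

    Endplate areas are estimated as ``pi * (width/2) * (depth/2)``.
    """
    if width <= 0 or depth <= 0:
        raise InvalidParameterError(
            f"width and depth must be positive, got {width}, {depth}"
        )
    return math.pi * (width / 2.0) * (depth / 2.0)


@dataclass(frozen=True)
class SpeciesPreset:
    """A named parameter set with per-field provenance notes.

    ``morphometry`` (giraffe only) carries the frustum specs of the neck and
    head so that the suspended mass and its CoM distance can be re-derived
    from geometry.
    """

    name: str
    params: SpineBaseParams
    provenance: dict[str, str] = field(default_factory=dict)
    morphometry: tuple[FrustumSpec, ...] = ()


def human_preset() -> SpeciesPreset:
    """Adult male human, L4/L5 level."""
    return SpeciesPreset(
        name="human",
        params=SpineBaseParams(
            mass=51.0,
            com_distance=0.265,
            pull_lever=0.049,
            disc_area=15e-4,
            label="L4/L5",
        ),
        provenance={
            "mass": "HAT mass of a 1.75 m / 75 kg male (2-D anthropometric model)",
            "com_distance": "HAT CoM distance from the L4/L5 joint centre",
            "pull_lever": "mean lever arm of lumped muscles/ligaments past L4/L5",
            "disc_area": "elliptic L4/L5 endplate area, 15 cm^2, from published "
                         "sagittal depth and frontal width",
        },
    )


# Frustum survey of the reference giraffe (adult female, ~800 kg, total
# length 4.30 m). Only derived quantities are published for this animal
# (neck length 1.55 m, head height 0.34 m, segment masses 120/27 kg, CoM
# offsets 0.60/0.215 m); the base/top dimensions below are calibrated so the
# frustum model reproduces all of them with water-like density.
GIRAFFE_NECK_FRUSTUM = FrustumSpec(
    sagittal_half_axis=0.147,   # base depth 0.294 m
    frontal_half_axis=0.294,    # base width 0.588 m (width:depth = 2)
    top_to_base_ratio=0.478,
    height=1.55,
    density=1000.0,
)

GIRAFFE_HEAD_FRUSTUM = FrustumSpec(
    sagittal_half_axis=0.17,    # base diameter 0.34 m = head height
    frontal_half_axis=0.17,     # circular cross-section
    top_to_base_ratio=0.315,
    height=0.63,
    density=1000.0,
)


def derive_hene_segment(
    morphometry: tuple[FrustumSpec, ...] = (GIRAFFE_NECK_FRUSTUM, GIRAFFE_HEAD_FRUSTUM),
) -> BodySegment:
    """Assemble the head–neck (HENE) segment from its frustum morphometry.

    The neck carries the head transversely at its top: the head CoM sits at
    neck length + half the head's sagittal diameter at the head CoM height.
    Returns the combined mass (~147 kg) and CoM offset from C7/T1 (~0.80 m).
    """
    neck_spec, head_spec = morphometry
    neck = segment_from_frustum(neck_spec)
    head = segment_from_frustum(head_spec)
    return assemble_inline_com(neck, head, transverse=True)


def giraffe_preset() -> SpeciesPreset:
    """Adult female giraffe, C7/T1 level, with re-derivable morphometry."""
    return SpeciesPreset(
        name="giraffe",
        params=SpineBaseParams(
            mass=147.0,
            com_distance=0.80,
            pull_lever=0.155,
            disc_area=ellipse_area(0.095, 0.070),
            label="C7/T1",
        ),
        provenance={
            "mass": "HENE mass: neck (120 kg) + head (27 kg) frustums at 1000 kg/m^3",
            "com_distance": "HENE CoM from C7/T1 by mass-weighted assembly of "
                            "neck (0.60 m) and head (1.55 m + d_head/2) parts",
            "pull_lever": "T1 endplate depth plus half its spinous-process "
                          "length (nuchal-ligament lever)",
            "disc_area": "C7/T1 endplate ellipse, width 9.5 cm x depth 7.0 cm",
        },
        morphometry=(GIRAFFE_NECK_FRUSTUM, GIRAFFE_HEAD_FRUSTUM),
    )


_AUSTRALOPITH_DEFAULTS = {
    # variant -> (pull_lever m, disc_area m^2, provenance note for the area)
    "afarensis": (0.037, 10.6e-4,
                  "L4 endplate ellipse, width 4.8 cm x depth 2.8 cm (10.6 cm^2)"),
    "boisei": (0.037, 5.2e-4,
               "largest of the early published L4 endplate areas (3.6-5.2 cm^2)"),
}


def australopith_preset(
    variant: str = "afarensis",
    lever: float | None = None,
    area: float | None = None,
) -> SpeciesPreset:
    """Australopith lumbar preset; *lever* (m) and *area* (m^2) may override defaults.

    Both variants share the 34 kg HAT (1.63 m / 50 kg body) and the
    human-like CoM distance 0.265 m.
    """
    if variant not in _AUSTRALOPITH_DEFAULTS:
        raise InvalidParameterError(
            f"unknown australopith variant {variant!r}; "
            f"expected one of {sorted(_AUSTRALOPITH_DEFAULTS)}"
        )
    default_lever, default_area, area_note = _AUSTRALOPITH_DEFAULTS[variant]
    return SpeciesPreset(
        name=f"australopith-{variant}",
        params=SpineBaseParams(
            mass=34.0,
            com_distance=0.265,
            pull_lever=lever if lever is not None else default_lever,
            disc_area=area if area is not None else default_area,
            label="L4",
        ),
        provenance={
            "mass": "HAT of the largest specimen considered: 1.63 m, 50 kg body",
            "com_distance": "assumed human-like HAT CoM distance",
            "pull_lever": "highest published lever arm, 3.7 cm",
            "disc_area": area_note,
        },
    )


BUILTIN_PRESETS = {
    "human": human_preset,
    "giraffe": giraffe_preset,
    "afarensis": lambda: australopith_preset("afarensis"),
    "boisei": lambda: australopith_preset("boisei"),
}


# ---------------------------------------------------------------------------
# Parameter-file IO
# ---------------------------------------------------------------------------
# Each physical key must carry a unit suffix; converters map to SI.
_PARAM_FIELDS = {
    # canonical name -> {accepted key: factor to SI}
    "mass": {"mass_kg": 1.0},
    "com_distance": {"com_distance_m": 1.0, "com_distance_cm": 1e-2},
    "pull_lever": {"pull_lever_m": 1.0, "pull_lever_cm": 1e-2},
    "disc_area": {"disc_area_m2": 1.0, "disc_area_cm2": 1e-4},
    "gravity": {"gravity_m_s2": 1.0},
    "pressure_factor": {"pressure_factor": 1.0},  # dimensionless
}
_REQUIRED_PARAMS = ("mass", "com_distance", "pull_lever", "disc_area")

_FRUSTUM_FIELDS = {
    "sagittal_half_axis": {"sagittal_half_axis_m": 1.0, "sagittal_half_axis_cm": 1e-2},
    "frontal_half_axis": {"frontal_half_axis_m": 1.0, "frontal_half_axis_cm": 1e-2},
    "top_to_base_ratio": {"top_to_base_ratio": 1.0},
    "height": {"height_m": 1.0, "height_cm": 1e-2},
    "density": {"density_kg_m3": 1.0},
}
_REQUIRED_FRUSTUM = ("sagittal_half_axis", "frontal_half_axis",
                     "top_to_base_ratio", "height")


def _parse_fields(mapping: dict, schema: dict, required: tuple, context: str) -> dict:
    known = {key: (canon, factor)
             for canon, keys in schema.items()
             for key, factor in keys.items()}
    out: dict[str, float] = {}
    for key, raw in mapping.items():
        if key not in known:
            hint = ""
            stem = key.rstrip("0123456789_").split("_")[0]
            if any(canon.startswith(stem) for canon in schema):
                hint = " (missing or unrecognised unit suffix?)"
            raise ParameterFileError(f"unknown field {key!r} in {context}{hint}")
        canon, factor = known[key]
        if canon in out:
            raise ParameterFileError(f"field {canon!r} given twice in {context}")
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ParameterFileError(
                f"field {key!r} in {context} is not a number: {raw!r}"
            ) from None
        out[canon] = value * factor
    for canon in required:
        if canon not in out:
            units = "/".join(schema[canon])
            raise ParameterFileError(
                f"missing required field {canon!r} ({units}) in {context}"
            )
    return out


def read_params(path) -> SpeciesPreset:
    """Read a species preset from a YAML parameter file.

    All physical keys require explicit unit suffixes; values are converted
    to SI. Unknown fields raise `ParameterFileError`.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterFileError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParameterFileError(f"{path}: expected a mapping at top level")
    allowed_top = {"name", "label", "provenance", "params", "morphometry"}
    unknown = set(doc) - allowed_top
    if unknown:
        raise ParameterFileError(f"{path}: unknown top-level fields {sorted(unknown)}")
    if "params" not in doc or not isinstance(doc["params"], dict):
        raise ParameterFileError(f"{path}: missing 'params' mapping")

    values = _parse_fields(doc["params"], _PARAM_FIELDS, _REQUIRED_PARAMS,
                           f"{path.name}:params")
    try:
        params = SpineBaseParams(label=str(doc.get("label", "")), **values)
    except InvalidParameterError as exc:
        raise ParameterFileError(f"{path}: {exc}") from exc

    frustums = []
    for i, entry in enumerate(doc.get("morphometry") or []):
        if not isinstance(entry, dict):
            raise ParameterFileError(f"{path}: morphometry[{i}] must be a mapping")
        entry = dict(entry)
        entry.pop("name", None)
        fvals = _parse_fields(entry, _FRUSTUM_FIELDS, _REQUIRED_FRUSTUM,
                              f"{path.name}:morphometry[{i}]")
        try:
            frustums.append(FrustumSpec(**fvals))
        except InvalidParameterError as exc:
            raise ParameterFileError(f"{path}: morphometry[{i}]: {exc}") from exc

    provenance = doc.get("provenance") or {}
    if not isinstance(provenance, dict):
        raise ParameterFileError(f"{path}: provenance must be a mapping")
    return SpeciesPreset(
        name=str(doc.get("name", path.stem)),
        params=params,
        provenance={str(k): str(v) for k, v in provenance.items()},
        morphometry=tuple(frustums),
    )


def write_params(preset: SpeciesPreset, path) -> None:
    """Write a preset to YAML in canonical SI keys; `read_params` inverts it."""
    p = preset.params
    doc: dict = {
        "name": preset.name,
        "label": p.label,
        "params": {
            "mass_kg": p.mass,
            "com_distance_m": p.com_distance,
            "pull_lever_m": p.pull_lever,
            "disc_area_m2": p.disc_area,
            "gravity_m_s2": p.gravity,
            "pressure_factor": p.pressure_factor,
        },
    }
    if preset.provenance:
        doc["provenance"] = dict(preset.provenance)
    if preset.morphometry:
        doc["morphometry"] = [
            {
                "sagittal_half_axis_m": f.sagittal_half_axis,
                "frontal_half_axis_m": f.frontal_half_axis,
                "top_to_base_ratio": f.top_to_base_ratio,
                "height_m": f.height,
                "density_kg_m3": f.density,
            }
            for f in preset.morphometry
        ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
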