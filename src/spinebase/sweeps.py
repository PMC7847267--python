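"""Angle sweeps, extremum location, inverse queries and species comparisons.

The compressive stress is ``P(phi) = (g/A)*(M*L*cos(phi)/R + M*sin(phi))``, a
single sinusoid ``K*sin(phi + delta)`` on [0, 90] deg. It peaks at
``phi* = atan(R_pull / L_com)`` and is strictly monotonic on either side, so
inverse queries (which angle yields a target stress?) are well posed once a
branch is chosen: the *erect* branch [phi*, 90] (where every everyday posture
lives) or the *flexed* branch [0, phi*]. Torque inversion is closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidParameterError, TargetOutOfRangeError
from .statics import LoadState, SpineBaseParams, compressive_stress, load_state

__all__ = [
    "SweepTable",
    "SpeciesComparison",
    "stress_sweep",
    "angle_of_max_stress",
    "angle_for_stress",
    "angle_for_torque",
    "compare_species",
]

SWEEP_COLUMNS = [
    "phi_deg",
    "torque_Nm",
    "pulling_force_N",
    "compressive_force_N",
    "shear_force_N",
    "stress_MPa",
    "weight_stress_MPa",
    "intradiscal_pressure_MPa",
]


@dataclass(frozen=True)
class SweepTable:
    """Load states over an inclusive [0, 90] deg angle grid for one parameter set."""

    records: tuple[tuple[float, LoadState], ...]
    params_label: str
    grid_step: float

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for phi, st in self.records:
            rows.append(
                {
                    "phi_deg": phi,
                    "torque_Nm": st.bending_torque,
                    "pulling_force_N": st.pulling_force,
                    "compressive_force_N": st.compressive_force,
                    "shear_force_N": st.shear_force,
                    "stress_MPa": st.compressive_stress / 1e6,
                    "weight_stress_MPa": st.weight_stress / 1e6,
                    "intradiscal_pressure_MPa": st.intradiscal_pressure / 1e6,
                }
            )
        return pd.DataFrame(rows, columns=SWEEP_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def stress_sweep(p: SpineBaseParams, step: float = 1.0) -> SweepTable:
    """Evaluate the full load state on the grid 0, step, 2*step, ..., 90 deg.

    Endpoints 0 and 90 are always included; if *step* does not divide 90 the
    final interval is shorter. Values are pointwise `statics.load_state`
    calls, so the table agrees bit-for-bit with single-angle evaluation.
    """
    if step <= 0 or step > 90:
        raise InvalidParameterError(f"step must lie in (0, 90], got {step}")
    n = int(round(90.0 / step))
    grid = [i * step for i in range(n + 1)] if math.isclose(n * step, 90.0) else None
    if grid is None:
        grid = list(np.arange(0.0, 90.0, step)) + [90.0]
    grid[-1] = 90.0
    records = tuple((phi, load_state(p, phi)) for phi in grid)
    return SweepTable(records=records, params_label=p.label, grid_step=step)


def angle_of_max_stress(p: SpineBaseParams) -> float:
    """Inclination of maximum compressive stress: atan(R_pull / L_com), degrees.

    Below this angle the rising weight term no longer offsets the falling
    pulling term; for the human parameters it is ~10.5 deg, i.e. an almost
    fully flexed trunk.
    """
    return math.degrees(math.atan2(p.pull_lever, p.com_distance))


def _branch_interval(p: SpineBaseParams, branch: str) -> tuple[float, float]:
    phi_star = angle_of_max_stress(p)
    if branch == "erect":
        return phi_star, 90.0
    if branch == "flexed":
        return 0.0, phi_star
    raise InvalidParameterError(f"branch must be 'erect' or 'flexed', got {branch!r}")


def angle_for_stress(p: SpineBaseParams, target: float, branch: str = "erect") -> float:
    """Inclination angle at which the compressive stress equals *target* (Pa).

    The stress is monotonic on each side of its maximum at
    ``phi* = atan(R_pull/L_com)``; *branch* selects the erect side
    [phi*, 90] (default) or the flexed side [0, phi*]. Root-finding is
    bracketed Brent iteration; the returned angle reproduces the target
    stress to ~1e-9 relative.
    """
    lo, hi = _branch_interval(p, branch)
    s_lo, s_hi = compressive_stress(p, lo), compressive_stress(p, hi)
    s_min, s_max = min(s_lo, s_hi), max(s_lo, s_hi)
    # tolerate float fuzz at the bracket edges (e.g. cos(90 deg) ~ 6e-17)
    eps = 1e-9 * s_max
    if s_min - eps <= target < s_min:
        target = s_min
    elif s_max < target <= s_max + eps:
        target = s_max
    if not s_min <= target <= s_max:
        raise TargetOutOfRangeError(
            f"target stress {target:.6g} Pa unattainable on the {branch} branch "
            f"[{lo:.3f}, {hi:.3f}] deg; attainable range is "
            f"[{s_min:.6g}, {s_max:.6g}] Pa"
        )
    f = lambda phi: compressive_stress(p, phi) - target
    if f(lo) == 0.0:
        return lo
    if f(hi) == 0.0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def angle_for_torque(p: SpineBaseParams, target: float) -> float:
    """Inclination angle at which the weight-induced joint torque equals *target* (N·m).

    Closed form: ``phi = acos(target / (M*g*L_com))``; the torque decreases
    monotonically from its maximum at full flexion to zero when erect.
    """
    tau_max = p.mass * p.gravity * p.com_distance
    if not 0.0 <= target <= tau_max:
        raise TargetOutOfRangeError(
            f"target torque {target:.6g} N·m outside attainable [0, {tau_max:.6g}]"
        )
    return math.degrees(math.acos(target / tau_max))


@dataclass(frozen=True)
class SpeciesComparison:
    """Stress comparison across (parameter set, angle) conditions.

    ``table`` lists each condition's stress and its ratio to the same
    species' fully erect (phi = 90 deg) value; ``pairwise`` holds the full
    matrix of stress ratios, entry [i, j] = stress_i / stress_j.
    """

    table: pd.DataFrame
    pairwise: pd.DataFrame = field(repr=False)


def compare_species(
    params: list[SpineBaseParams], phis: list[float]
) -> SpeciesComparison:
    """Pairwise compressive-stress ratios for paired (params, angle) conditions.

    The two lists must have equal length; condition *i* is species
    ``params[i]`` held at ``phis[i]`` degrees.
    """
    if len(params) != len(phis):
        raise InvalidParameterError(
            f"params and phis must have equal length ({len(params)} vs {len(phis)})"
        )
    labels = [f"{p.label or f'set{i}'}@{phi:g}deg" for i, (p, phi) in enumerate(zip(params, phis))]
    stresses = np.array([compressive_stress(p, phi) for p, phi in zip(params, phis)])
    vs_erect = np.array(
        [compressive_stress(p, phi) / compressive_stress(p, 90.0) for p, phi in zip(params, phis)]
    )
    table = pd.DataFrame(
        {
            "label": [p.label for p in params],
            "phi_deg": phis,
            "stress_MPa": stresses / 1e6,
            "vs_own_erect": vs_erect,
        },
        index=labels,
    )
    pairwise = pd.DataFrame(
        stresses[:, None] / stresses[None, :], index=labels, columns=labels
    )
    return SpeciesComparison(table=table, pairwise=pairwise)
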