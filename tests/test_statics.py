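"""Static-equilibrium load quantities: identities, limits and published values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinebase import (
    AngleDomainError,
    InvalidParameterError,
    SpineBaseParams,
    bending_torque,
    compressive_force,
    compressive_stress,
    intradiscal_pressure,
    load_state,
    pulling_force,
    sensitivity_multiplier,
    shear_force,
    weight_stress,
)

params_strategy = st.builds(
    SpineBaseParams,
    mass=st.floats(1.0, 500.0),
    com_distance=st.floats(0.05, 2.0),
    pull_lever=st.floats(0.005, 0.5),
    disc_area=st.floats(1e-4, 1e-2),
)


class TestErectAndFlexedLimits:
    def test_fully_erect_has_no_torque_pulling_or_shear(self, human):
        st90 = load_state(human, 90.0)
        assert st90.bending_torque == pytest.approx(0.0, abs=1e-9)
        assert st90.pulling_force == pytest.approx(0.0, abs=1e-9)
        assert st90.shear_force == pytest.approx(0.0, abs=1e-9)
        assert st90.compressive_force == pytest.approx(
            human.mass * human.gravity, rel=1e-12
        )

    def test_fully_flexed_shear_is_full_weight_and_weight_stress_zero(self, human):
        assert shear_force(human, 0.0) == pytest.approx(
            human.mass * human.gravity, rel=1e-12
        )
        assert weight_stress(human, 0.0) == 0.0
        # at phi=0 the compressive force is purely pulling-induced
        assert compressive_force(human, 0.0) == pytest.approx(
            pulling_force(human, 0.0), rel=1e-14
        )

    @pytest.mark.parametrize("phi", [-1.0, 90.5, 180.0])
    def test_angle_outside_validity_range_rejected(self, human, phi):
        with pytest.raises(AngleDomainError):
            bending_torque(human, phi)


class TestPublishedHumanValues:
    """Model outputs for the human L4/L5 preset match the reported predictions."""

    def test_full_flexion_point(self, human):
        assert bending_torque(human, 0.0) == pytest.approx(132.6, rel=0.02)
        assert pulling_force(human, 0.0) == pytest.approx(2706.0, rel=0.02)
        assert compressive_stress(human, 0.0) / 1e6 == pytest.approx(1.81, rel=0.02)

    def test_erect_stress_and_pressure(self, human):
        assert compressive_stress(human, 90.0) / 1e6 == pytest.approx(0.34, rel=0.02)
        assert intradiscal_pressure(human, 90.0) / 1e6 == pytest.approx(0.47, rel=0.02)

    def test_moderate_flexion(self, human):
        assert compressive_stress(human, 60.0) / 1e6 == pytest.approx(1.2, rel=0.02)
        assert intradiscal_pressure(human, 60.0) / 1e6 == pytest.approx(1.7, rel=0.02)
        assert pulling_force(human, 60.0) == pytest.approx(1352.9, rel=0.001)

    def test_thirty_newton_metre_posture(self, human):
        assert bending_torque(human, 77.0) == pytest.approx(30.0, rel=0.02)
        assert compressive_stress(human, 77.0) / 1e6 == pytest.approx(0.73, rel=0.02)
        assert weight_stress(human, 77.0) / 1e6 == pytest.approx(0.33, rel=0.02)

    def test_shear_at_sixty_degrees(self, human):
        assert shear_force(human, 60.0) == pytest.approx(250.2, rel=0.001)


class TestConsistencyIdentities:
    @settings(max_examples=200, derandomize=True)
    @given(p=params_strategy, phi=st.floats(0.0, 90.0))
    def test_torque_reconstruction_and_closed_form(self, p, phi):
        """F_pull * R_pull == torque; composed stress equals the closed form."""
        assert pulling_force(p, phi) * p.pull_lever == pytest.approx(
            bending_torque(p, phi), rel=1e-12, abs=1e-9
        )
        phi_r = math.radians(phi)
        closed = (p.gravity / p.disc_area) * (
            p.mass * p.com_distance * math.cos(phi_r) / p.pull_lever
            + p.mass * math.sin(phi_r)
        )
        assert compressive_stress(p, phi) == pytest.approx(closed, rel=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(p=params_strategy, phi=st.floats(0.0, 90.0))
    def test_weight_decomposition(self, p, phi):
        """Shear and axial weight components recompose the full weight."""
        w_axial = p.mass * p.gravity * math.sin(math.radians(phi))
        total = shear_force(p, phi) ** 2 + w_axial**2
        assert total == pytest.approx((p.mass * p.gravity) ** 2, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(p=params_strategy, phi=st.floats(0.0, 90.0))
    def test_load_state_is_internally_consistent(self, p, phi):
        state = load_state(p, phi)
        assert state.pulling_force * p.pull_lever == pytest.approx(
            state.bending_torque, rel=1e-12, abs=1e-9
        )
        assert state.compressive_stress == pytest.approx(
            state.compressive_force / p.disc_area, rel=1e-14
        )
        assert state.intradiscal_pressure == pytest.approx(
            p.pressure_factor * state.compressive_stress, rel=1e-14
        )
        assert state.compressive_stress >= state.weight_stress - 1e-9

    def test_erect_stress_is_pure_weight(self, human):
        assert compressive_stress(human, 90.0) == pytest.approx(
            human.mass * human.gravity / human.disc_area, rel=1e-14
        )


class TestScalingLaws:
    def test_stress_linear_in_mass_and_inverse_area(self, human):
        doubled_m = SpineBaseParams(
            mass=2 * human.mass, com_distance=human.com_distance,
            pull_lever=human.pull_lever, disc_area=human.disc_area,
        )
        halved_a = SpineBaseParams(
            mass=human.mass, com_distance=human.com_distance,
            pull_lever=human.pull_lever, disc_area=human.disc_area / 2,
        )
        for phi in (0.0, 33.3, 60.0, 90.0):
            base = compressive_stress(human, phi)
            assert compressive_stress(doubled_m, phi) == pytest.approx(2 * base, rel=1e-12)
            assert compressive_stress(halved_a, phi) == pytest.approx(2 * base, rel=1e-12)

    def test_pulling_force_scales_inversely_with_lever(self, human):
        doubled_r = SpineBaseParams(
            mass=human.mass, com_distance=human.com_distance,
            pull_lever=2 * human.pull_lever, disc_area=human.disc_area,
        )
        assert pulling_force(doubled_r, 40.0) == pytest.approx(
            pulling_force(human, 40.0) / 2, rel=1e-12
        )


class TestSensitivityMultiplier:
    def test_human_exceeds_giraffe(self, human, giraffe):
        assert sensitivity_multiplier(human) > sensitivity_multiplier(giraffe)

    def test_doubling_area_halves_multiplier(self, human):
        doubled = SpineBaseParams(
            mass=human.mass, com_distance=human.com_distance,
            pull_lever=human.pull_lever, disc_area=2 * human.disc_area,
        )
        assert sensitivity_multiplier(doubled) == pytest.approx(
            sensitivity_multiplier(human) / 2, rel=1e-12
        )

    def test_g_times_s_is_pulling_stress_at_full_flexion(self, human):
        """g*S*cos(phi) is the pulling-induced stress; at phi=0 it is the whole stress."""
        g_s = human.gravity * sensitivity_multiplier(human)
        assert g_s == pytest.approx(compressive_stress(human, 0.0), rel=1e-12)
        assert g_s / 1e6 == pytest.approx(1.804, abs=0.001)

    def test_pulling_stress_slope_proportional_to_s(self, human, giraffe):
        """Pulling-induced stress is linear in cos(phi) with slope g*S for any species."""
        for p in (human, giraffe):
            phis = np.array([10.0, 35.0, 70.0])
            pulling_stress = np.array(
                [(compressive_stress(p, f) - weight_stress(p, f)) for f in phis]
            )
            slope = p.gravity * sensitivity_multiplier(p)
            assert pulling_stress == pytest.approx(
                slope * np.cos(np.radians(phis)), rel=1e-12
            )


def test_invalid_params_rejected():
    with pytest.raises(InvalidParameterError):
        SpineBaseParams(mass=-1.0, com_distance=0.3, pull_lever=0.05, disc_area=1e-3)
    with pytest.raises(InvalidParameterError):
        SpineBaseParams(mass=51.0, com_distance=0.3, pull_lever=0.05, disc_area=0.0)
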