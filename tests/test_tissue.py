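"""Only-tension elements, tension classification and thermal shortening."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pfjsim as pj
from pfjsim.materials import UnknownTissueError
from pfjsim.tissue import (
    ConvergenceError,
    TensionState,
    classify_tension,
    iterate_thermal,
    ligament_force,
    ligament_stress,
    lr_alpha,
    thermal_deltaT,
)


class TestMaterialTable:
    @pytest.mark.parametrize("tissue,k", [
        ("quadriceps_tendon", 1350.0),
        ("patellar_tendon", 2000.0),
        ("lateral_retinaculum", 2.0),
        ("native_mpfl", 12.0),
        ("semitendinosus_graft", 100.0),
        ("gracilis_graft", 80.0),
        ("quadriceps_tendon_graft", 33.6),
    ])
    def test_stiffnesses(self, materials, tissue, k):
        assert materials.stiffness(tissue) == k
        assert materials.poisson(tissue) == 0.3

    def test_table_is_closed(self, materials):
        with pytest.raises(UnknownTissueError):
            materials.stiffness("acl")


class TestLigamentForce:
    def test_anatomic_full_extension_pretension(self):
        # semitendinosus graft stretched 2.5 mm past the 40 deg reference
        assert ligament_force(60.2 - 57.7, 100.0) == pytest.approx(250.0)

    def test_anatomic_thirty_degrees(self):
        assert ligament_force(0.2, 100.0) == pytest.approx(20.0)

    def test_slack_element_carries_nothing(self):
        assert ligament_force(-1.0, 100.0) == 0.0

    @given(dl=st.floats(-20, 20), k=st.floats(0.1, 5000))
    def test_only_tension_and_monotone(self, dl, k):
        f = ligament_force(dl, k)
        assert f >= 0.0
        assert f >= ligament_force(dl - 0.5, k)


class TestLigamentStress:
    def test_semitendinosus_pretension_stress(self):
        assert ligament_stress(250.0, 1.0) == pytest.approx(79.577, abs=0.01)

    def test_native_mpfl_stress(self):
        # 2.5 mm x 12 N/mm through the 1 mm beam section
        assert ligament_stress(2.5 * 12.0) == pytest.approx(9.549, abs=0.01)

    def test_zero_force(self):
        assert ligament_stress(0.0) == 0.0

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            ligament_stress(-1.0)


class TestClassification:
    @pytest.mark.parametrize("target,ref,expected", [
        (57.3, 57.7, TensionState.SLACK),       # shorter than reference
        (60.2, 57.7, TensionState.PRETENSION),  # longer than reference
        (36.33, 36.33, TensionState.PRETENSION),  # boundary: zero elongation
    ])
    def test_geometric_rule(self, target, ref, expected):
        assert classify_tension(target, ref) is expected

    def test_hint_override_for_thermal(self, caplog):
        with caplog.at_level("WARNING", logger="pfjsim.tissue"):
            state = classify_tension(35.6, 36.2, footnote_hint="c")
        assert state is TensionState.THERMAL
        assert any("overrides" in r.message for r in caplog.records)

    def test_agreeing_hint_logs_nothing(self, caplog):
        with caplog.at_level("WARNING", logger="pfjsim.tissue"):
            classify_tension(60.2, 57.7, footnote_hint="b")
        assert not caplog.records

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_tension(-1.0, 57.7)
        with pytest.raises(ValueError):
            classify_tension(57.0, 57.7, footnote_hint="x")


class TestThermal:
    def test_temperature_drop_for_nanp_reference(self):
        assert thermal_deltaT(0.8, 36.2, 0.0005) == pytest.approx(44.2, abs=0.05)

    def test_zero_shortening(self):
        assert thermal_deltaT(0.0, 36.2) == 0.0

    def test_doubling_alpha_halves_deltaT(self):
        assert thermal_deltaT(0.8, 36.2, 0.001) == pytest.approx(
            0.5 * thermal_deltaT(0.8, 36.2, 0.0005))

    def test_iteration_converges_on_linear_plant(self):
        """Bisection oracle: a spring against a linear restraint, where the
        achieved length has a closed form; larger shortening gives larger
        converged temperature drop."""
        l0, alpha, k_elem, k_wall = 36.2, 0.0005, 100.0, 300.0

        def plant(target):
            def achieved(dT):
                # equilibrium of element (rest l0*(1-a*dT)) vs wall spring
                contraction = alpha * dT * l0
                return l0 - contraction * k_elem / (k_elem + k_wall)
            return achieved

        dts = []
        for target in (36.0, 35.7, 35.4):
            achieved = plant(target)
            dt = iterate_thermal(achieved, target, l0, alpha, tol=0.001)
            assert abs(achieved(dt) - target) < 0.001
            dts.append(dt)
        assert dts[0] < dts[1] < dts[2]

    def test_target_at_unloaded_length_needs_no_drop(self):
        assert iterate_thermal(lambda dT: 36.2 - 0.0005 * 36.2 * dT * 0.5,
                               36.2, 36.2) == 0.0

    def test_cannot_lengthen(self):
        with pytest.raises(ConvergenceError):
            iterate_thermal(lambda dT: 36.2, 40.0, 36.2)


class TestLrAlpha:
    def test_equal_lengths_recover_mpfl_alpha(self):
        dt = thermal_deltaT(0.8, 36.2, 0.0005)
        assert lr_alpha(0.8, dt, 36.2) == pytest.approx(0.0005)

    def test_zero_shift(self):
        assert lr_alpha(0.0, 0.0, 36.2) == 0.0

    def test_round_trip_identity(self):
        a = lr_alpha(1.3, 57.0, 41.0)
        assert a * 57.0 * 41.0 == pytest.approx(1.3, abs=1e-12)

    def test_undefined_without_temperature(self):
        with pytest.raises(ValueError):
            lr_alpha(0.8, 0.0, 36.2)


class TestFootnoteReproduction:
    def test_geometric_rule_reproduces_all_technique_footnotes(
            self, technique_lengths):
        """Every slack/pretension footnote in the mean-technique length
        table follows from the sign of the elongation at the 40 deg
        reference."""
        for technique, sub in technique_lengths.groupby("technique"):
            ref = float(sub.loc[sub.angle_deg == 40, "length_mm"].iloc[0])
            for row in sub.itertuples():
                if row.note in ("a", "b"):
                    got = classify_tension(float(row.length_mm), ref)
                    expected = (TensionState.SLACK if row.note == "a"
                                else TensionState.PRETENSION)
                    assert got is expected, (technique, row.angle_deg)

    def test_geometric_rule_reproduces_all_clinical_footnotes(
            self, clinical_lengths):
        groups = clinical_lengths.groupby(["case", "bundle"])
        for (case, bundle), sub in groups:
            ref = float(sub.loc[sub.angle_deg == 40, "length_mm"].iloc[0])
            for row in sub.itertuples():
                if row.note in ("a", "b"):
                    got = classify_tension(float(row.length_mm), ref)
                    expected = (TensionState.SLACK if row.note == "a"
                                else TensionState.PRETENSION)
                    assert got is expected, (case, bundle, row.angle_deg)
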