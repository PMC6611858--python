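"""End-to-end simulations: techniques, clinical cases, classification, sweeps."""

import numpy as np
import pytest

import pfjsim as pj
from pfjsim.tissue import TensionState, ligament_stress


class TestRunCase:
    def test_native_tension_pattern(self, technique_results):
        """The native ligament loads the joint only in early flexion."""
        res = technique_results["native"]
        assert res.angle(0.0).mpfl_stress_mpa > 0
        assert res.angle(30.0).mpfl_stress_mpa > 0
        for angle in (60.0, 90.0, 120.0):
            assert res.angle(angle).mpfl_stress_mpa == 0.0
            assert res.angle(angle).lr_stress_mpa == 0.0

    def test_non_physiometric_stress_grows_with_flexion(self, technique_results):
        res = technique_results["non_anatomic_non_physiometric"]
        s = [res.angle(a).mpfl_stress_mpa for a in (60.0, 90.0, 120.0)]
        assert 0 < s[0] < s[1] < s[2]
        assert res.angle(60.0).thermal_deltaT_c > 0

    def test_constant_length_table_gives_zero_everything(self, mean_knee):
        lengths = {"single": {a: (50.0, "") for a in (0.0, 30.0, 40.0, 60.0,
                                                      90.0, 120.0)}}
        spec = pj.ReconstructionSpec(technique="custom", graft="semitendinosus_graft",
                                     bundle_config="SB", lengths=lengths)
        res = pj.run_case(mean_knee, spec, angles=[0.0, 60.0])
        for a in res.angles:
            assert a.mpfl_stress_mpa == 0.0
            assert a.peak_relative_mpa == 0.0

    def test_slack_angles_report_exactly_zero_stress(self, technique_results):
        for tech in ("native", "anatomic", "non_anatomic_physiometric"):
            for angle in (60.0, 90.0, 120.0):
                a = technique_results[tech].angle(angle)
                assert a.state == "slack"
                assert a.mpfl_stress_mpa == 0.0

    def test_determinism_bit_identical_summaries(self, mean_knee):
        spec = pj.ReconstructionSpec.from_technique("native")
        r1 = pj.run_case(mean_knee, spec, angles=[0.0])
        r2 = pj.run_case(mean_knee, spec, angles=[0.0])
        assert r1.config_hash == r2.config_hash
        assert r1.summary().equals(r2.summary())
        assert np.array_equal(r1.angle(0.0).relative.pressure,
                              r2.angle(0.0).relative.pressure)

    def test_missing_reference_angle_rejected(self):
        lengths = {"single": {a: (50.0, "") for a in (0.0, 30.0, 60.0, 90.0,
                                                      120.0)}}
        with pytest.raises(ValueError):
            pj.ReconstructionSpec(technique="custom", graft="semitendinosus_graft",
                                  bundle_config="SB", lengths=lengths)

    def test_stress_matches_fixed_geometry_oracle_for_pretension(
            self, technique_results, materials):
        """For every pretension angle the reported graft stress equals
        Δl·K/(πr²) from the length table."""
        for tech, res in technique_results.items():
            k = materials.stiffness(res.spec.graft)
            for bundle in res.spec.bundles:
                ref = res.spec.reference_length(bundle)
                for a in res.angles:
                    prot = a.protocols[bundle]
                    if prot.state is TensionState.PRETENSION:
                        oracle = ligament_stress(k * (prot.target_length - ref))
                        assert a.mpfl_stress_mpa == pytest.approx(oracle,
                                                                  rel=1e-12)


class TestPhysiometry:
    def test_anatomic_column_is_physiometric(self):
        spec = pj.ReconstructionSpec.from_technique("anatomic")
        assert pj.physiometric_check(spec) is True

    def test_non_physiometric_column_is_not(self):
        spec = pj.ReconstructionSpec.from_technique("non_anatomic_non_physiometric")
        assert pj.physiometric_check(spec) is False

    def test_constant_table_never_tense(self):
        table = {a: 50.0 for a in (0.0, 30.0, 40.0, 60.0, 90.0, 120.0)}
        assert pj.physiometric_check(table) is False


class TestIsometry:
    def test_anatomic_range_exceeds_five_millimetres(self):
        # 60.2 .. 50.7 over the arc: 9.5 mm of length change
        spec = pj.ReconstructionSpec.from_technique("anatomic")
        assert pj.isometric_check(spec) is False

    def test_non_physiometric_technique_is_isometric(self):
        # 37.5 .. 35.4: 2.1 mm of length change
        spec = pj.ReconstructionSpec.from_technique("non_anatomic_non_physiometric")
        assert pj.isometric_check(spec) is True

    def test_constant_table_is_isometric(self):
        table = {a: 50.0 for a in (0.0, 30.0, 40.0, 60.0, 90.0, 120.0)}
        assert pj.isometric_check(table) is True


class TestSweep:
    def test_friction_sweep_is_flat(self, mean_knee):
        spec = pj.ReconstructionSpec.from_technique("native")
        results, table = pj.sweep("friction", [0.01, 0.02, 0.025, 0.03],
                                  mean_knee, spec, angles=[30.0])
        assert len(results) == 4
        peaks = table.peak_pressure_mpa.values
        assert (peaks.max() - peaks.min()) / peaks.mean() < 0.05

    def test_empty_values_empty_result(self, mean_knee):
        spec = pj.ReconstructionSpec.from_technique("native")
        results, table = pj.sweep("friction", [], mean_knee, spec)
        assert results == [] and table.empty

    def test_peak_pressure_decreases_with_thickness(self, mean_knee):
        spec = pj.ReconstructionSpec.from_technique("native")
        _, table = pj.sweep("patellar_thickness", [2.0, 3.0, 4.0],
                            mean_knee, spec, angles=[30.0])
        peaks = table.peak_pressure_mpa.values
        assert peaks[0] > peaks[1] > peaks[2]

    def test_unknown_parameter_rejected(self, mean_knee):
        spec = pj.ReconstructionSpec.from_technique("native")
        with pytest.raises(KeyError):
            pj.sweep("gravity", [9.8], mean_knee, spec)


@pytest.fixture(scope="module")
def case1():
    return pj.clinical_report(1)


class TestClinicalCases:
    def test_case1_tension_pattern_and_growth(self, case1):
        res = case1.result
        for angle in (0.0, 30.0):
            assert res.angle(angle).mpfl_stress_mpa == 0.0
        s = [res.angle(a).mpfl_stress_mpa for a in (60.0, 90.0, 120.0)]
        assert 0 < s[0] < s[1] < s[2]
        assert case1.physiometric is False

    def test_case1_pressure_risk_flagged(self, case1):
        assert case1.pressure_risk is True

    def test_case4_is_physiometric(self):
        rep = pj.clinical_report(4, angles=[0.0, 30.0])
        assert rep.physiometric is True
        assert rep.result.angle(0.0).mpfl_stress_mpa > 0

    def test_case3_quadriceps_graft_tense_only_early(self):
        rep = pj.clinical_report(3)
        res = rep.result
        assert res.spec.graft == "quadriceps_tendon_graft"
        assert res.angle(0.0).mpfl_stress_mpa > 0
        assert res.angle(30.0).mpfl_stress_mpa > 0
        for angle in (60.0, 90.0, 120.0):
            assert res.angle(angle).mpfl_stress_mpa == 0.0

    def test_double_bundle_cases_classify_per_bundle(self):
        spec = pj.ReconstructionSpec.from_clinical_case(2)
        assert set(spec.bundles) == {"proximal", "distal"}
        assert pj.physiometric_check(spec) is False


class TestOrdering:
    def test_relative_pressure_ordering_at_full_extension(self, technique_results):
        """Peak relative pressure at 0 deg grows from native through
        anatomic to the non-anatomic physiometric reconstruction."""
        p = {t: technique_results[t].angle(0.0).peak_relative_mpa
             for t in technique_results}
        assert p["native"] < p["anatomic"] < p["non_anatomic_physiometric"]

    def test_all_converged_residuals_small(self, technique_results):
        for res in technique_results.values():
            for a in res.angles:
                assert a.pose.residual_n < 0.01
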