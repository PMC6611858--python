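"""Foundation contact pressure and quasi-static equilibrium."""

import numpy as np
import pytest

import pfjsim as pj
from pfjsim.contact import (
    IndeterminateEquilibriumError,
    foundation_pressure,
    combined_foundation_stiffness,
    relative_field,
)
from pfjsim.materials import CartilageMaterial, ContactSettings


class TestFoundationPressure:
    def test_closed_form_two_layer_stack(self):
        # 0.1 mm into two 3 mm layers in series: (0.55*10)/(1.45*0.1*6)*0.1
        mat = CartilageMaterial(thickness=6.0)
        assert foundation_pressure(0.1, mat) == pytest.approx(0.632, abs=0.001)

    def test_no_penetration_no_pressure(self):
        mat = CartilageMaterial()
        assert foundation_pressure(0.0, mat) == 0.0
        assert foundation_pressure(-0.5, mat) == 0.0

    def test_linearity(self):
        mat = CartilageMaterial()
        assert foundation_pressure(0.2, mat) == pytest.approx(
            2 * foundation_pressure(0.1, mat))

    def test_series_compliance_matches_summed_thickness(self):
        a, b = CartilageMaterial(thickness=3.0), CartilageMaterial(thickness=3.0)
        assert combined_foundation_stiffness(a, b) == pytest.approx(
            CartilageMaterial(thickness=6.0).confined_modulus / 6.0)

    def test_incompressible_material_rejected(self):
        with pytest.raises(ValueError):
            CartilageMaterial(poisson_ratio=0.5)


class TestBaseline:
    def test_zero_approach_gives_zero_field(self, mean_geometry):
        model = pj.ContactModel(mean_geometry,
                                settings=ContactSettings(approach=0.0))
        _, field = model.baseline()
        assert field.total_force == 0.0
        assert (field.pressure == 0).all()

    def test_approach_generates_positive_symmetric_contact(self, contact_model):
        field = contact_model.field(contact_model._baseline_pose.translation)
        assert field.total_force > 0
        ratio = field.peak("medial") / field.peak("lateral")
        assert abs(ratio - 1.0) < 0.2

    def test_pressure_zero_where_gap(self, contact_model):
        field = contact_model.field(contact_model._baseline_pose.translation)
        assert (field.pressure[field.penetration <= 0] == 0).all()
        assert (field.pressure >= 0).all()

    def test_total_force_is_pressure_integral(self, contact_model):
        field = contact_model.field(contact_model._baseline_pose.translation)
        assert field.total_force == pytest.approx(
            float(np.sum(field.pressure * field.node_area)))

    def test_revolution_symmetry_of_penetration(self, mean_geometry):
        """Sliding the patella along the groove arc (rotation about the
        epicondylar axis) leaves the penetration field unchanged."""
        pts = mean_geometry.patellar_cartilage.nodes + np.array([0.0, 19.0, 0.0])
        pen0, _ = mean_geometry.trochlea.penetration(pts)
        ang = np.radians(25.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        pen1, _ = mean_geometry.trochlea.penetration(pts @ rot.T)
        assert np.allclose(pen0, pen1, atol=1e-9)


class TestEquilibrium:
    def test_no_load_keeps_baseline_pose(self, contact_model):
        pose, field = contact_model.solve_equilibrium(applied_force=np.zeros(3))
        base = contact_model._baseline_pose.translation
        assert np.allclose(pose.translation, base, atol=1e-6)
        base_field = contact_model.field(base)
        assert np.allclose(field.pressure, base_field.pressure)

    def test_medial_force_moves_patella_medially(self, contact_model):
        base = contact_model.field(contact_model._baseline_pose.translation)
        pose, loaded = contact_model.solve_equilibrium(
            applied_force=np.array([30.0, 0.0, 0.0]))
        shift = pose.translation - contact_model._baseline_pose.translation
        assert shift[0] > 0
        med = lambda f: float(np.sum((f.pressure * f.node_area)[f.medial]))
        assert med(loaded) / loaded.total_force > med(base) / base.total_force

    def test_force_balance_residual(self, contact_model):
        pose, loaded = contact_model.solve_equilibrium(
            applied_force=np.array([25.0, 0.0, 0.0]))
        resultant = loaded.resultant()
        assert abs(resultant[0] + 25.0) < 0.01
        assert pose.residual_n < 0.01

    def test_energy_stationarity(self, contact_model):
        f = np.array([40.0, 0.0, 0.0])
        pose, _ = contact_model.solve_equilibrium(applied_force=f)

        def energy(tx):
            t = pose.translation.copy()
            t[0] = tx
            field = contact_model.field(t)
            pen = np.maximum(field.penetration, 0.0)
            e = 0.5 * contact_model.stiffness * np.sum(field.node_area * pen**2)
            return e - float(f @ t)

        h = 1e-4
        x = pose.translation[0]
        grad = (energy(x + h) - energy(x - h)) / (2 * h)
        scale = max(abs(energy(x)), 1.0)
        assert abs(grad) / scale < 1e-6

    def test_contact_force_monotone_in_pretension(self, contact_model):
        forces = []
        for magnitude in (0.0, 50.0, 150.0, 300.0):
            _, loaded = contact_model.solve_equilibrium(
                applied_force=np.array([0.6, 0.0, 0.0]) * magnitude)
            forces.append(loaded.total_force)
        assert all(b >= a - 1e-9 for a, b in zip(forces, forces[1:]))

    def test_indeterminate_without_contact_or_tension(self, mean_geometry):
        model = pj.ContactModel(mean_geometry,
                                settings=ContactSettings(approach=0.0))
        model.baseline()
        with pytest.raises(IndeterminateEquilibriumError):
            model.solve_equilibrium()


class TestRelativeField:
    def test_identical_fields_cancel(self, contact_model):
        f = contact_model.field(contact_model._baseline_pose.translation)
        rel = relative_field(f, f)
        assert (rel.pressure == 0).all()

    def test_nodewise_difference(self, contact_model):
        base = contact_model.field(contact_model._baseline_pose.translation)
        _, loaded = contact_model.solve_equilibrium(
            applied_force=np.array([60.0, 0.0, 0.0]))
        rel = relative_field(loaded, base)
        assert np.array_equal(rel.pressure, loaded.pressure - base.pressure)
        # load shifted medially: some lateral nodes lose pressure
        assert rel.pressure.min() < 0 < rel.pressure.max()

    def test_mesh_mismatch_rejected(self, contact_model, mean_knee):
        other = pj.ContactModel(pj.build_knee(mean_knee, element_size=2.0))
        _, coarse = other.baseline()
        fine = contact_model.field(contact_model._baseline_pose.translation)
        with pytest.raises(ValueError):
            relative_field(fine, coarse)


class TestFriction:
    def test_friction_bounds_tangential_load(self, contact_model):
        field = contact_model.field(contact_model._baseline_pose.translation)
        assert field.friction_bound == pytest.approx(0.02 * field.total_force)

    def test_peak_pressure_insensitive_to_friction(self, mean_geometry):
        peaks = []
        for mu in (0.01, 0.02, 0.025, 0.03):
            model = pj.ContactModel(mean_geometry,
                                    settings=ContactSettings(friction=mu))
            model.baseline()
            _, loaded = model.solve_equilibrium(
                applied_force=np.array([30.0, 0.0, 0.0]))
            peaks.append(loaded.peak())
        spread = (max(peaks) - min(peaks)) / np.mean(peaks)
        assert spread < 0.05
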