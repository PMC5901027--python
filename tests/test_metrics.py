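"""Safety metrics: closed-form geometry, risk ramp, AHC contact, aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import littplan as lp
from littplan.anatomy import HeadModel, LabelVolume, RoiMask, SkullModel, distance_field, extract_roi
from littplan.metrics import (
    RiskParams,
    Trajectory,
    ahc_center_proportion,
    brainstem_distance,
    compute_metrics,
    drilling_angle,
    intracerebral_length,
    min_critical_distance,
    overall_risk,
    pointwise_risk,
)
from conftest import parallel_trajectory

SPHERE = SkullModel.sphere((0.0, 0.0, 0.0), 70.0, 76.0)


class TestSkullGeometry:
    def test_radial_trajectory_length_equals_inner_radius(self):
        traj = Trajectory((0.0, -90.0, 0.0), (0.0, 0.0, 0.0))
        assert intracerebral_length(traj, SPHERE) == pytest.approx(70.0, abs=0.05)

    def test_target_set_back_along_ray(self):
        # target 10 mm inside the crossing along the same ray
        traj = Trajectory((0.0, -90.0, 0.0), (0.0, -60.0, 0.0))
        assert intracerebral_length(traj, SPHERE) == pytest.approx(10.0, abs=0.05)

    @pytest.mark.parametrize("impact", [10.0, 20.0, 40.0])
    def test_chord_matches_line_sphere_intersection(self, impact):
        traj = Trajectory((impact, -90.0, 0.0), (impact, 10.0, 0.0))
        expected = 10.0 + np.sqrt(70.0**2 - impact**2)
        assert intracerebral_length(traj, SPHERE) == pytest.approx(expected, abs=0.05)

    def test_target_outside_inner_skull_raises(self):
        with pytest.raises(ValueError, match="outside"):
            intracerebral_length(Trajectory((0, -90, 0), (0, -75, 0)), SPHERE)

    def test_radial_drilling_angle_is_zero(self):
        traj = Trajectory((0.0, -90.0, 0.0), (0.0, 0.0, 0.0))
        assert drilling_angle(traj, SPHERE) == pytest.approx(0.0, abs=1.0)

    @pytest.mark.parametrize("angle_deg", [15.0, 30.0, 45.0])
    def test_oblique_drilling_angle_matches_sphere_normal(self, angle_deg):
        impact = 76.0 * np.sin(np.radians(angle_deg))
        traj = Trajectory((impact, -90.0, 0.0), (impact, 0.0, 0.0))
        assert drilling_angle(traj, SPHERE) == pytest.approx(angle_deg, abs=1.0)


class TestRiskRamp:
    def test_documented_endpoint_values(self):
        p = RiskParams()
        assert pointwise_risk(2.0, p) == 1.0
        assert pointwise_risk(12.0, p) == 0.0
        assert pointwise_risk(6.5, p) == pytest.approx(0.5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            pointwise_risk(-1.0)

    @given(st.floats(0.0, 25.0), st.floats(0.0, 25.0))
    def test_ramp_is_non_increasing_bounded_and_lipschitz(self, d1, d2):
        p = RiskParams()
        r1, r2 = pointwise_risk(d1, p), pointwise_risk(d2, p)
        assert 0.0 <= r1 <= 1.0
        if d1 <= d2:
            assert r1 >= r2
        assert abs(r1 - r2) <= abs(d1 - d2) / (p.d_hi - p.d_lo) + 1e-12


class TestOverallRisk:
    def test_far_trajectory_has_zero_risk(self, planar_model):
        traj = parallel_trajectory(25.0)
        assert overall_risk(traj, planar_model.critical_field, planar_model.skull) == 0.0

    def test_saturated_corridor_equals_length_over_norm(self, planar_model):
        # the whole intracerebral segment is 1 mm from the sheet: risk 1 per mm
        traj = parallel_trajectory(1.0)
        length = intracerebral_length(traj, planar_model.skull)
        risk = overall_risk(traj, planar_model.critical_field, planar_model.skull)
        assert risk == pytest.approx(length / 10.0, rel=0.01)

    def test_linear_in_norm_length(self, planar_model):
        traj = parallel_trajectory(1.0)
        r10 = overall_risk(traj, planar_model.critical_field, planar_model.skull,
                           RiskParams(norm_length=10.0))
        r20 = overall_risk(traj, planar_model.critical_field, planar_model.skull,
                           RiskParams(norm_length=20.0))
        assert r10 == pytest.approx(2.0 * r20)

    def test_step_refinement_stability_on_phantom(self, base_model, base_plan):
        traj = base_plan.trajectory
        coarse = overall_risk(traj, base_model.critical_field, base_model.skull,
                              RiskParams(sample_step=1.0))
        fine = overall_risk(traj, base_model.critical_field, base_model.skull,
                            RiskParams(sample_step=0.1))
        assert coarse == pytest.approx(fine, rel=0.02)


class TestMinDistances:
    def test_through_critical_sheet_is_zero(self, planar_model):
        traj = Trajectory((-20.0, -60.0, 0.0), (20.0, 10.0, 0.0))
        d = min_critical_distance(traj, planar_model.critical_field, planar_model.skull)
        assert d == pytest.approx(0.0, abs=0.1)

    def test_single_voxel_source_point_line_distance(self):
        data = np.zeros((81, 81, 81), dtype=np.int16)
        affine = np.eye(4)
        affine[:3, 3] = -40.0
        data[40, 40, 40] = 6  # critical voxel at the origin
        vol = LabelVolume(data, affine, {"critical": frozenset({6})})
        fld = distance_field(extract_roi(vol, "critical"))
        skull = SkullModel.sphere((0, 0, 0), 38.0, 40.0)
        traj = Trajectory((5.0, -50.0, 0.0), (5.0, 20.0, 0.0))
        d = min_critical_distance(traj, fld, skull)
        assert d == pytest.approx(5.0, abs=0.15)

    def test_min_not_greater_than_segment_mean(self, base_model, base_plan):
        traj = base_plan.trajectory
        from littplan.metrics import _segment_samples
        _, pts, _, _, _ = _segment_samples(traj, base_model.skull, 1.0)
        mean = float(np.mean(base_model.critical_field.at(pts)))
        d = min_critical_distance(traj, base_model.critical_field, base_model.skull)
        assert d <= mean + 1e-9

    def test_brainstem_line_cylinder_closed_form(self):
        # vertical cylinder radius 8 about the z-axis; line at 17.75 mm offset
        data = np.zeros((101, 101, 101), dtype=np.int16)
        affine = np.eye(4)
        affine[:3, 3] = -50.0
        vol0 = LabelVolume(data, affine, {"brainstem": frozenset({7})})
        x, y, z = np.meshgrid(*[np.arange(101) - 50.0] * 3, indexing="ij")
        cyl = (np.sqrt(x**2 + y**2) <= 8.0) & (np.abs(z) <= 30.0)
        data[cyl] = 7
        vol = LabelVolume(data, affine, {"brainstem": frozenset({7})})
        fld = distance_field(extract_roi(vol, "brainstem"))
        skull = SkullModel.sphere((0, 0, 0), 48.0, 49.5)
        traj = Trajectory((17.75, -47.0, 0.0), (17.75, 30.0, 0.0))
        d = brainstem_distance(traj, fld, skull)
        assert d == pytest.approx(9.75, abs=0.25)

    def test_lateral_entry_never_decreases_brainstem_distance(self, base_model):
        target = np.array([-23.0, 11.0, -21.0])
        dists = []
        for lateral in np.linspace(-36.0, -50.0, 8):
            traj = Trajectory((lateral, -70.0, -2.0), tuple(target))
            dists.append(brainstem_distance(traj, base_model.brainstem_field,
                                            base_model.skull))
        assert all(b >= a - 1e-6 for a, b in zip(dists, dists[1:]))


class TestAhcContact:
    @staticmethod
    def _tube_roi(length=40.0, radius=4.0):
        n = 61
        data = np.zeros((n, n, n), dtype=bool)
        affine = np.eye(4)
        affine[:3, 3] = -(n - 1) / 2.0
        x, y, z = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0] * 3, indexing="ij")
        tube = (np.sqrt(x**2 + z**2) <= radius) & (np.abs(y) <= length / 2.0)
        return RoiMask("ahc", tube, affine)

    def test_outside_trajectory_scores_zero(self):
        roi = self._tube_roi()
        traj = Trajectory((30.0, -30.0, 30.0), (30.0, 30.0, 30.0))
        assert ahc_center_proportion(traj, roi) == 0.0

    def test_axial_cannulation_of_straight_tube(self):
        roi = self._tube_roi()
        traj = Trajectory((0.0, -20.0, 0.0), (0.0, 20.0, 0.0))
        assert ahc_center_proportion(traj, roi) >= 0.9

    def test_non_increasing_in_core_margin(self):
        roi = self._tube_roi()
        traj = Trajectory((0.0, -20.0, 0.0), (0.0, 20.0, 0.0))
        props = [ahc_center_proportion(traj, roi, m) for m in (0.5, 1.5, 2.5, 3.5)]
        assert all(b <= a + 1e-9 for a, b in zip(props, props[1:]))

    def test_empty_core_falls_back_to_full_mask_with_warning(self):
        roi = self._tube_roi(radius=1.0)
        traj = Trajectory((0.0, -20.0, 0.0), (0.0, 20.0, 0.0))
        with pytest.warns(UserWarning, match="core"):
            p = ahc_center_proportion(traj, roi, core_margin=3.0)
        assert 0.0 < p <= 1.0


class TestAggregation:
    def test_bundle_matches_individual_operations(self, base_model, base_plan):
        traj = base_plan.trajectory
        m = compute_metrics(traj, base_model)
        assert m.errors == {}
        assert m.intracerebral_length == pytest.approx(
            intracerebral_length(traj, base_model.skull))
        assert m.overall_risk == pytest.approx(
            overall_risk(traj, base_model.critical_field, base_model.skull))
        assert m.min_critical_distance == pytest.approx(
            min_critical_distance(traj, base_model.critical_field, base_model.skull))
        assert m.brainstem_distance == pytest.approx(
            brainstem_distance(traj, base_model.brainstem_field, base_model.skull))
        m2 = compute_metrics(traj, base_model)
        assert m2 == m  # determinism

    def test_ventricle_passage_is_detected(self, base_model, base_phantom):
        _, gt = base_phantom
        node = np.asarray(gt["ventricle_curve"][1])
        entry = node + np.array([0.0, -55.0, 0.0])
        entry = entry / np.linalg.norm(entry) * 81.0
        m = compute_metrics(Trajectory(tuple(entry), tuple(node)), base_model)
        assert m.ventricle_hit is True

    def test_missing_components_reported_not_fatal(self, planar_model):
        m = compute_metrics(parallel_trajectory(5.0), planar_model)
        assert m.min_critical_distance is not None
        assert "brainstem_distance" in m.errors
        assert "ahc_center_proportion" in m.errors

    def test_rigid_translation_invariance(self):
        shift = np.array([7.0, -11.0, 13.0])
        vol, _ = lp.planar_risk_phantom()
        affine2 = vol.affine.copy()
        affine2[:3, 3] += shift
        vol2 = LabelVolume(vol.data, affine2, vol.role_map)

        def model_for(v, center):
            return HeadModel(volume=v, skull=SkullModel.sphere(center, 70.0, 76.0),
                             side="left",
                             ventricles=extract_roi(v, "ventricles"),
                             critical_field=distance_field(extract_roi(v, "critical")))

        m1 = compute_metrics(parallel_trajectory(4.0), model_for(vol, (0, 0, 0)))
        t = parallel_trajectory(4.0)
        t2 = Trajectory(tuple(np.asarray(t.entry) + shift),
                        tuple(np.asarray(t.target) + shift))
        m2 = compute_metrics(t2, model_for(vol2, tuple(shift)))
        assert m1.intracerebral_length == pytest.approx(m2.intracerebral_length, abs=1e-6)
        assert m1.min_critical_distance == pytest.approx(m2.min_critical_distance, abs=1e-6)
        assert m1.overall_risk == pytest.approx(m2.overall_risk, abs=1e-9)
        assert m1.drilling_angle == pytest.approx(m2.drilling_angle, abs=1e-6)
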