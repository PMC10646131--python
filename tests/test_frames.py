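"""Anatomic axes, sagittal/axial frames, simulated resection, tibial frame."""

import numpy as np
import pytest
import trimesh
from shapely.geometry import Polygon

from kneekin import frames as fr
from kneekin import synthetic as syn
from kneekin._geom import PD, Line, Plane, rotation_about, rotation_matrix, transform_points, unit
from kneekin.errors import ConvergenceError, GeometryError, ParameterError
from kneekin.pipeline import build_native_frame, flexion_from_axes


def _cylinder(radius, z0, z1, center_xy=(0.0, 0.0), sections=96):
    mesh = trimesh.creation.cylinder(radius=radius, height=z1 - z0, sections=sections)
    mesh.vertices += np.array([center_xy[0], center_xy[1], (z0 + z1) / 2])
    return mesh


class TestCrossSectionMidpoint:
    def test_cylinder_midpoint_on_axis(self):
        cyl = _cylinder(15.0, 0.0, 100.0)
        mid = fr.cross_section_midpoint(cyl, Plane([0, 0, 37.0], PD))
        assert np.allclose(mid, [0, 0, 37.0], atol=1e-6)

    def test_translation_equivariance(self):
        cyl = _cylinder(15.0, 0.0, 100.0, center_xy=(0.0, 5.0))
        mid = fr.cross_section_midpoint(cyl, Plane([0, 0, 50.0], PD))
        assert np.allclose(mid, [0, 5.0, 50.0], atol=1e-6)

    def test_matches_independent_polygon_centroid(self, knee_model):
        """Area centroid of the femoral shaft section at the 70 mm level
        vs an independent polygon library."""
        plane = Plane([0, 0, 70.0], PD)
        mid = fr.cross_section_midpoint(knee_model.femur, plane)
        section = knee_model.femur.section(plane_origin=plane.point,
                                           plane_normal=plane.normal)
        polys = [Polygon(p[:-1, :2]) for p in section.discrete
                 if np.allclose(p[0], p[-1])]
        biggest = max(polys, key=lambda p: p.area)
        assert mid[0] == pytest.approx(biggest.centroid.x, abs=1e-9)
        assert mid[1] == pytest.approx(biggest.centroid.y, abs=1e-9)

    def test_no_intersection_is_geometry_error(self):
        cyl = _cylinder(15.0, 0.0, 100.0)
        with pytest.raises(GeometryError):
            fr.cross_section_midpoint(cyl, Plane([0, 0, 500.0], PD))


class TestAnatomicAxis:
    def test_straight_shaft_axis_parallel_to_shaft(self, knee_model):
        axis = fr.anatomic_axis(knee_model.femur, 0.0, fr.FEMUR_AXIS_LEVELS,
                                toward="proximal")
        angle = np.degrees(np.arccos(np.clip(axis.direction @ PD, -1, 1)))
        assert angle < 0.1

    def test_bowed_shaft_gives_chord_not_tangent(self):
        """A shaft offset above 100 mm: the axis joins the midpoints at the
        two levels (the chord), matching the analytic midpoints."""
        lower = _cylinder(12.0, 0.0, 100.0)
        upper = _cylinder(12.0, 100.0, 160.0, center_xy=(0.0, 5.0))
        bone = trimesh.util.concatenate([lower, upper])
        axis = fr.anatomic_axis(bone, 0.0, (70.0, 120.0), toward="proximal")
        expected = unit(np.array([0.0, 5.0, 120.0]) - np.array([0.0, 0.0, 70.0]))
        assert np.allclose(axis.point, [0, 0, 70.0], atol=1e-6)
        assert np.allclose(axis.direction, expected, atol=1e-6)

    def test_identical_levels_rejected(self, knee_model):
        with pytest.raises(ParameterError, match="distinct"):
            fr.anatomic_axis(knee_model.femur, 0.0, (70.0, 70.0))

    def test_level_beyond_bone_names_level(self, knee_model):
        with pytest.raises(GeometryError, match="200"):
            fr.anatomic_axis(knee_model.femur, 0.0, (70.0, 200.0))


class TestFlexionAngle:
    def test_straight_limb_zero(self):
        assert fr.flexion_angle([0, 0, 1.0], [0, 0, -1.0]) == pytest.approx(0.0)

    def test_right_angle(self):
        assert fr.flexion_angle([0, 0, 1.0], [0, -1.0, 0]) == pytest.approx(90.0)

    def test_symmetric_and_scale_invariant(self, rng):
        u, v = rng.normal(size=3), rng.normal(size=3)
        assert fr.flexion_angle(u, v) == pytest.approx(fr.flexion_angle(v, u))
        assert fr.flexion_angle(3.7 * u, v) == pytest.approx(fr.flexion_angle(u, 0.2 * v))

    def test_zero_axis_rejected(self):
        with pytest.raises(ParameterError):
            fr.flexion_angle([0, 0, 0.0], [0, 0, 1.0])

    def test_hinged_synthetic_knee_recovers_imposed_flexion(self, knee_model):
        """Hinge the femur 45 deg about the trans-condylar axis; the
        axis-based flexion angle recovers it within 0.5 deg."""
        from kneekin.io import PoseFrame, PoseSequence
        lm = knee_model.landmarks
        pose = rotation_about(lm.condylar_axis.point, lm.condylar_axis.direction, 45.0)
        seq = PoseSequence([PoseFrame(0, np.nan, {"femur": pose, "tibia": np.eye(4)})])
        flex = flexion_from_axes(knee_model, seq)
        assert flex[0] == pytest.approx(45.0, abs=0.5)


class TestFemoralSagittalFrame:
    def test_normal_matches_analytic_centers(self, knee_model):
        lm = knee_model.landmarks
        frame = fr.femoral_sagittal_frame(knee_model.medial_condyle,
                                          knee_model.lateral_condyle)
        expected = unit(lm.lateral_condyle_center - lm.medial_condyle_center)
        angle = np.degrees(np.arccos(np.clip(frame.ml @ expected, -1, 1)))
        assert angle < 0.5

    def test_rotated_model_round_trip(self, knee_model):
        """Pre-rotating the femur 10 deg about PD rotates the recovered
        frame by the same amount (round-trip identity within 0.5 deg)."""
        R = rotation_matrix(PD, 10.0)
        med = knee_model.medial_condyle.copy()
        lat = knee_model.lateral_condyle.copy()
        med.vertices = med.vertices @ R.T
        lat.vertices = lat.vertices @ R.T
        base = fr.femoral_sagittal_frame(knee_model.medial_condyle,
                                         knee_model.lateral_condyle)
        rot = fr.femoral_sagittal_frame(med, lat)
        angle = np.degrees(np.arccos(np.clip(rot.ml @ (R @ base.ml), -1, 1)))
        assert angle < 0.5

    def test_sparse_patch_rejected(self):
        tiny = trimesh.creation.icosphere(subdivisions=1, radius=20.0)  # 42 verts
        with pytest.raises(GeometryError, match="vertices"):
            fr.femoral_sagittal_frame(tiny, tiny)

    def test_equivariance_under_rigid_transform(self, knee_model):
        T = rotation_about([5.0, -3.0, 7.0], [1.0, 2.0, 2.0], 25.0)
        T[:3, 3] += [4.0, -6.0, 2.0]
        med = knee_model.medial_condyle.copy()
        lat = knee_model.lateral_condyle.copy()
        med.vertices = transform_points(T, med.vertices)
        lat.vertices = transform_points(T, lat.vertices)
        base = fr.femoral_sagittal_frame(knee_model.medial_condyle,
                                         knee_model.lateral_condyle)
        moved = fr.femoral_sagittal_frame(
            med, lat, proximal_hint=T[:3, :3] @ PD,
            posterior_hint=T[:3, :3] @ np.array([0.0, -1.0, 0.0]))
        assert np.allclose(moved.origin, transform_points(T, base.origin), atol=1e-6)
        for ax in ("ml", "ap", "pd"):
            assert np.allclose(getattr(moved, ax), T[:3, :3] @ getattr(base, ax),
                               atol=2e-6)


class TestMedialPlateauPlane:
    def test_planar_patch_exact(self, symmetric_knee):
        plane = fr.medial_plateau_plane(symmetric_knee.medial_plateau_patch)
        assert np.allclose(plane.normal, PD, atol=1e-9)
        assert abs(plane.point[2]) < 1e-9

    def test_noisy_patch_tilt_bounded(self, rng):
        """+-0.2 mm vertex noise on a 37x50 mm patch tilts the fit < 0.5 deg."""
        base = syn._surface_grid(-37.5, 0.0, -25.0, 25.0, lambda x: 0.0 * x, step=5.0)
        worst = 0.0
        for _ in range(20):
            verts = base.vertices.copy()
            verts[:, 2] += rng.uniform(-0.2, 0.2, len(verts))
            plane = fr.fit_plane(verts)
            n = plane.normal if plane.normal[2] > 0 else -plane.normal
            worst = max(worst, np.degrees(np.arccos(np.clip(n @ PD, -1, 1))))
        assert worst < 0.5

    def test_correction_is_rotation_about_ap_only(self, knee_model):
        """With a tilted sagittal frame the corrected normal differs from
        the raw fit only by a rotation about AP: the AP component of the
        normal is preserved and the ML component becomes zero."""
        sag = fr.femoral_sagittal_frame(knee_model.medial_condyle,
                                        knee_model.lateral_condyle)
        # patch tilted 4 deg about ML so its raw normal has an AP component
        tilted = syn._surface_grid(-37.5, 0.0, -25.0, 25.0,
                                   lambda x: 0.0 * x, step=5.0)
        R = rotation_matrix([1.0, 0, 0], 4.0)
        tilted.vertices = tilted.vertices @ R.T
        raw = fr.fit_plane(tilted.vertices)
        raw_n = raw.normal if raw.normal[2] > 0 else -raw.normal
        corrected = fr.medial_plateau_plane(tilted, sagittal=sag)
        assert abs(corrected.normal @ sag.ml) < 1e-9
        assert corrected.normal @ sag.ap == pytest.approx(raw_n @ sag.ap, abs=1e-9)

    def test_collinear_patch_rejected(self):
        pts = np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)])
        with pytest.raises(GeometryError, match="collinear"):
            fr.medial_plateau_plane(pts)


def _sweep_oracle(medial_plane, c_med, c_lat, ap_axis, params):
    """Independent exhaustive sweep: evaluate every candidate angle in
    search order with plain trigonometry, return the first success or None."""
    p0 = np.asarray(c_med, float) - params.distal_offset * medial_plane.normal
    for theta in fr.vv_candidate_angles(params):
        n = rotation_matrix(ap_axis, theta) @ medial_plane.normal
        tm = abs((np.asarray(c_med) - p0) @ n)
        tl = abs((np.asarray(c_lat) - p0) @ n)
        if abs(tm - tl) <= params.thickness_tolerance:
            return theta, abs(tm - tl)
    return None


class TestSimulateResection:
    def test_symmetric_tibia_balances_at_zero(self, symmetric_knee):
        lm = symmetric_knee.landmarks
        res = fr.simulate_resection_plane(lm.medial_plateau_plane,
                                          lm.tibial_medial_center,
                                          lm.tibial_lateral_center,
                                          np.array([0, 1.0, 0]))
        assert res.vv_adjustment_deg == 0.0
        assert res.imbalance == pytest.approx(0.0, abs=1e-9)
        assert res.thickness_medial == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("varus", [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    def test_matches_exhaustive_sweep_oracle(self, varus):
        spec = syn.KneeSpec(medial_condyle_radius=23.0, lateral_condyle_radius=23.0,
                            plateau_varus_angle=varus)
        lm = syn.generate_knee_model(spec).landmarks
        params = fr.ResectionParams()
        args = (lm.medial_plateau_plane, lm.tibial_medial_center,
                lm.tibial_lateral_center, np.array([0, 1.0, 0]))
        expected = _sweep_oracle(*args, params)
        if expected is None:
            with pytest.raises(ConvergenceError):
                fr.simulate_resection_plane(*args, params)
        else:
            res = fr.simulate_resection_plane(*args, params)
            assert res.vv_adjustment_deg == expected[0]
            assert res.imbalance <= params.thickness_tolerance

    def test_extreme_deformity_raises_convergence_error(self):
        spec = syn.KneeSpec(medial_condyle_radius=23.0, lateral_condyle_radius=23.0,
                            plateau_varus_angle=30.0)
        lm = syn.generate_knee_model(spec).landmarks
        with pytest.raises(ConvergenceError) as err:
            fr.simulate_resection_plane(lm.medial_plateau_plane,
                                        lm.tibial_medial_center,
                                        lm.tibial_lateral_center,
                                        np.array([0, 1.0, 0]))
        assert err.value.best_imbalance_mm > 0.5


class TestTibialFrame:
    def test_rectangular_plateau_origin_and_ap_depth(self, symmetric_knee):
        frame = build_native_frame(symmetric_knee)
        spec = symmetric_knee.spec
        assert frame.meta["ap_depth"] == pytest.approx(spec.plateau_ap_depth, abs=1e-6)
        assert frame.meta["ml_width"] == pytest.approx(spec.plateau_ml_width, abs=1e-6)
        assert np.allclose(frame.origin[:2], [0.0, 0.0], atol=1e-6)
        assert frame.origin[2] == pytest.approx(-10.0, abs=1e-6)

    def test_ap_axis_lies_in_resection_plane(self, knee_model):
        frame = build_native_frame(knee_model)
        assert abs(frame.ap @ frame.pd) < 1e-9

    def test_contour_translation_moves_origin(self, symmetric_knee):
        """Translating the tibia anteriorly by 3 mm translates the frame
        origin by the same amount."""
        lm = symmetric_knee.landmarks
        sag = fr.femoral_sagittal_frame(symmetric_knee.medial_condyle,
                                        symmetric_knee.lateral_condyle)
        res = fr.simulate_resection_plane(lm.medial_plateau_plane,
                                          lm.tibial_medial_center,
                                          lm.tibial_lateral_center, sag.ap)
        base = fr.tibial_frame(res, symmetric_knee.tibia, sag)
        moved_tibia = symmetric_knee.tibia.copy()
        moved_tibia.vertices = moved_tibia.vertices + np.array([0, 3.0, 0])
        moved = fr.tibial_frame(res, moved_tibia, sag)
        assert np.allclose(moved.origin - base.origin, [0, 3.0, 0], atol=1e-6)

    def test_ap_depth_equals_contour_extremum_oracle(self, knee_model):
        """A-P box extent equals the brute-force max-min of the contour's
        AP coordinates."""
        lm = knee_model.landmarks
        sag = fr.femoral_sagittal_frame(knee_model.medial_condyle,
                                        knee_model.lateral_condyle)
        plane = fr.medial_plateau_plane(knee_model.medial_plateau_patch, sag)
        res = fr.simulate_resection_plane(plane, lm.tibial_medial_center,
                                          lm.tibial_lateral_center, sag.ap)
        frame = fr.tibial_frame(res, knee_model.tibia, sag)
        section = knee_model.tibia.section(plane_origin=res.plane.point,
                                           plane_normal=res.plane.normal)
        pts = np.vstack([p[:-1] for p in section.discrete if np.allclose(p[0], p[-1])])
        v = (pts - res.plane.point) @ frame.ap
        assert frame.meta["ap_depth"] == pytest.approx(v.max() - v.min(), abs=1e-9)
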