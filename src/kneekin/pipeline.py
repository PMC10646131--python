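"""End-to-end analysis: meshes + pose sequences -> tracks, rotation
profiles and cohort comparisons.

For a native knee the tibial reference is built from the meshes (femoral
sagittal frame -> medial plateau plane -> simulated resection plane ->
tibial frame) and the condylar track is the average of the repeated
registrations.  For a TKA knee the reference is the baseplate
bounding-box frame and a single registration pass is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import Frame
from .errors import ParameterError
from .frames import (FEMUR_AXIS_LEVELS, TIBIA_AXIS_LEVELS, ResectionParams,
                     anatomic_axis, baseplate_frame, femoral_sagittal_frame,
                     flexion_angle, medial_plateau_plane, simulate_resection_plane,
                     tibial_frame)
from .io import PoseSequence
from .kinematics import (ACTIVITY_SCHEDULES, CondylarTrack, RotationProfile,
                         StandardizationParams, average_repeats,
                         build_rotation_profile, standardize_ap,
                         track_from_sequence)
from .stats import GroupSample, PowerSpec, TestResult, detectable_difference, \
    power_at, two_sample_t


def _patch_centroid(patch) -> np.ndarray:
    """Area-weighted surface centroid of an articular patch."""
    areas = patch.area_faces
    return (patch.triangles_center * areas[:, None]).sum(axis=0) / areas.sum()


def build_native_frame(model, params: ResectionParams = ResectionParams()) -> Frame:
    """Tibial coordinate system of a native knee, mesh-derived."""
    sagittal = femoral_sagittal_frame(model.medial_condyle, model.lateral_condyle)
    medial_plane = medial_plateau_plane(model.medial_plateau_patch, sagittal)
    c_med = _patch_centroid(model.medial_plateau_patch)
    c_lat = _patch_centroid(model.lateral_plateau_patch)
    resection = simulate_resection_plane(medial_plane, c_med, c_lat,
                                         sagittal.ap, params)
    return tibial_frame(resection, model.tibia, sagittal)


def reference_frame(model, params: ResectionParams = ResectionParams()) -> Frame:
    return baseplate_frame(model) if model.kind == "tka" else build_native_frame(model, params)


def flexion_from_axes(model, seq: PoseSequence) -> np.ndarray:
    """Recompute per-frame flexion from the anatomic axes (femur 7/12 cm
    above, tibia 5/12 cm below the joint line), for sequences whose
    flexion annotation is absent."""
    jl = model.landmarks.joint_line_z
    fem_axis = anatomic_axis(model.femur, jl, FEMUR_AXIS_LEVELS, toward="proximal")
    tib_mesh = model.tibia if model.kind == "native" else None
    if tib_mesh is None:
        raise ParameterError("flexion recomputation needs a tibial bone mesh")
    tib_axis = anatomic_axis(tib_mesh, jl, TIBIA_AXIS_LEVELS, toward="distal")
    out = []
    for frame in seq.frames:
        rf = frame.poses[model.moving_body][:3, :3] @ fem_axis.direction
        rt = frame.poses[model.fixed_body][:3, :3] @ tib_axis.direction
        out.append(flexion_angle(rf, rt))
    return np.array(out)


@dataclass
class KneeAnalysis:
    track: CondylarTrack
    standardized_track: CondylarTrack
    profile: RotationProfile
    frame: Frame
    report: dict = field(default_factory=dict)


def analyze_knee(model, repeats: list[PoseSequence] | PoseSequence,
                 activity: str,
                 resection_params: ResectionParams = ResectionParams(),
                 reference_ap_depth: float = 50.0,
                 knee_id: str | None = None,
                 group: str | None = None) -> KneeAnalysis:
    """Full per-knee analysis: reference frame, lowest-point track
    (averaged over registration repeats for native knees), standardized
    track and rotation profile."""
    if activity not in ACTIVITY_SCHEDULES:
        raise ParameterError(f"unknown activity {activity!r}")
    if isinstance(repeats, PoseSequence):
        repeats = [repeats]
    if model.kind == "tka" and len(repeats) > 1:
        repeats = repeats[:1]  # CAD registration is single-pass
    frame = reference_frame(model, resection_params)
    schedule = ACTIVITY_SCHEDULES[activity]
    meta = dict(activity=activity, knee_id=knee_id, group=group,
                reference=frame.meta.get("reference", "native_resection_plane"))
    tracks = [track_from_sequence(model, seq, frame, schedule, **meta)
              for seq in repeats]
    track = average_repeats(tracks) if len(tracks) > 1 else tracks[0]
    std = standardize_ap(track, StandardizationParams(
        reference_ap_depth, frame.meta["ap_depth"]))
    profile = build_rotation_profile(track, activity)
    report = {
        "reference": frame.meta.get("reference"),
        "origin_mm": [float(x) for x in frame.origin],
        "axes": {k: [float(x) for x in getattr(frame, k)] for k in ("ml", "ap", "pd")},
        "ap_depth_mm": float(frame.meta["ap_depth"]),
        "vv_adjustment_deg": frame.meta.get("vv_adjustment_deg"),
        "repeats": track.repeats,
    }
    return KneeAnalysis(track, std, profile, frame, report)


def analyze_cohort(members, activity: str | None = None,
                   resection_params: ResectionParams = ResectionParams()) -> list[KneeAnalysis]:
    out = []
    for m in members:
        out.append(analyze_knee(m.model, m.repeats, activity or m.motion.activity,
                                resection_params=resection_params,
                                knee_id=m.knee_id, group=m.group))
    return out


def profiles_dataframe(analyses: list[KneeAnalysis]) -> pd.DataFrame:
    return pd.concat([a.profile.to_dataframe() for a in analyses], ignore_index=True)


def arcs_dataframe(analyses: list[KneeAnalysis]) -> pd.DataFrame:
    return pd.concat([a.profile.arcs_dataframe() for a in analyses], ignore_index=True)


def compare_cohorts(profiles_a: list[RotationProfile],
                    profiles_b: list[RotationProfile],
                    labels: tuple[str, str] = ("a", "b"),
                    kind: str = "welch",
                    power: PowerSpec | None = PowerSpec()) -> dict:
    """The cohort comparison: maximum-flexion rotation plus each arc of
    extension, as two-sample tests, with the power section appended."""
    if not profiles_a or not profiles_b:
        raise ParameterError("both cohorts need at least one profile")
    activity = profiles_a[0].activity

    def _test(va, vb) -> TestResult:
        return two_sample_t(GroupSample(labels[0], va), GroupSample(labels[1], vb), kind)

    max_a = [p.max_flexion_rotation for p in profiles_a]
    max_b = [p.max_flexion_rotation for p in profiles_b]
    report: dict = {
        "activity": activity,
        "groups": {labels[0]: len(profiles_a), labels[1]: len(profiles_b)},
        "max_flexion": _test(max_a, max_b).as_dict(),
        "arcs": [],
    }
    arcs_a = {(hi, lo): [p.arcs[i][2] for p in profiles_a]
              for i, (hi, lo, _) in enumerate(profiles_a[0].arcs)}
    for i, (hi, lo, _) in enumerate(profiles_b[0].arcs):
        va = arcs_a[(hi, lo)]
        vb = [p.arcs[i][2] for p in profiles_b]
        report["arcs"].append({"flexion_hi": hi, "flexion_lo": lo,
                               **_test(va, vb).as_dict()})
    if power is not None:
        mdd = detectable_difference(power)
        report["power"] = {
            "spec": power.__dict__,
            "detectable_difference_deg": mdd,
            "power_at_detectable": power_at(mdd, power),
        }
    return report
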