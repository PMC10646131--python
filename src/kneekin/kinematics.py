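"""Lowest-point condylar tracking and tibial internal-external rotation.

The kinematic quantity of interest is the anterior-posterior (A-P)
position of each femoral condyle on the tibia, indicated per frame by the
*lowest point* of the condylar surface with respect to the tibial
reference plane (the simulated resection plane for native knees, the
baseplate plane for TKA knees).  Tibial internal-external (I-E) rotation
between two flexion angles is the angle between the medial-lateral lines
connecting the two condylar positions at each angle; internal rotation of
the tibia (lateral femoral condyle moving posterior) is positive, in
right-knee convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geom import Frame, Plane, transform_points
from .errors import ContractError, ParameterError

#: Flexion angles (degrees, decreasing) at which frames are analysed.
ACTIVITY_SCHEDULES: dict[str, tuple[float, ...]] = {
    "step_up": (60.0, 45.0, 30.0, 15.0, 0.0),
    "chair_rise": (90.0, 60.0, 30.0, 0.0),
}

#: Default tolerance within which surface points tie for "lowest" (mm).
TIE_TOLERANCE_MM = 0.05

#: A schedule angle with no pose frame within this window cannot be analysed.
FLEXION_MATCH_WINDOW_DEG = 5.0


def lowest_point(mesh, pose: np.ndarray, reference: Plane,
                 tie_tol: float = TIE_TOLERANCE_MM) -> np.ndarray:
    """Point of the posed surface minimizing signed distance to ``reference``.

    Vertices within ``tie_tol`` mm of the minimum are treated as tied and
    resolved by their centroid, which makes the result robust to mesh
    jitter on near-flat or near-tangent regions.

    Parameters
    ----------
    mesh : trimesh.Trimesh or (n, 3) array
        Condylar surface in body coordinates.
    pose : (4, 4) array
        Rigid transform mapping body coordinates into the frame in which
        ``reference`` is expressed.
    reference : Plane
        Oriented reference plane; its normal points proximally ("up").
    """
    verts = np.asarray(getattr(mesh, "vertices", mesh), dtype=float)
    if verts.size == 0:
        raise ParameterError("lowest_point: empty mesh")
    posed = transform_points(np.asarray(pose, dtype=float), verts)
    d = reference.signed_distance(posed)
    dmin = d.min()
    tied = posed[d <= dmin + tie_tol]
    return tied.mean(axis=0)


def condylar_positions(model, poses: dict[str, np.ndarray], frame: Frame,
                       tie_tol: float = TIE_TOLERANCE_MM):
    """Lowest-point (AP, ML) coordinates of both femoral condyles in a
    tibial reference frame, for one pose frame.

    ``poses`` maps body names to lab-frame transforms; the femoral body is
    re-expressed in the tibial body's coordinates (the frame and its
    reference plane are defined in tibial body coordinates).

    Returns ``((ap_med, ml_med), (ap_lat, ml_lat))`` in mm.
    """
    t_fem = poses[model.moving_body]
    t_tib = poses[model.fixed_body]
    rel = np.linalg.inv(t_tib) @ t_fem
    plane = Plane(frame.origin, frame.pd)
    out = []
    for condyle in (model.medial_condyle, model.lateral_condyle):
        p = lowest_point(condyle, rel, plane, tie_tol=tie_tol)
        ml, ap, _ = frame.to_local(p)
        out.append((float(ap), float(ml)))
    return out[0], out[1]


@dataclass
class CondylarTrack:
    """Per-schedule-angle condylar coordinates in the tibial frame."""

    flexion_deg: np.ndarray
    ap_med: np.ndarray
    ml_med: np.ndarray
    ap_lat: np.ndarray
    ml_lat: np.ndarray
    reference: str = "native_resection_plane"  # or "tka_baseplate_bbox"
    standardized: bool = False
    repeats: int = 1
    activity: str | None = None
    knee_id: str | None = None
    group: str | None = None

    def __post_init__(self):
        for name in ("flexion_deg", "ap_med", "ml_med", "ap_lat", "ml_lat"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.flexion_deg)
        if any(len(getattr(self, c)) != n for c in ("ap_med", "ml_med", "ap_lat", "ml_lat")):
            raise ParameterError("track columns have mismatched lengths")

    def _index_of(self, flexion: float) -> int:
        hits = np.flatnonzero(np.isclose(self.flexion_deg, flexion, atol=1e-9))
        if hits.size == 0:
            raise ParameterError(
                f"flexion angle {flexion} deg not in track schedule {list(self.flexion_deg)}")
        return int(hits[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "knee_id": self.knee_id, "group": self.group, "activity": self.activity,
            "flexion_deg": self.flexion_deg,
            "ap_med_mm": self.ap_med, "ml_med_mm": self.ml_med,
            "ap_lat_mm": self.ap_lat, "ml_lat_mm": self.ml_lat,
            "standardized": int(self.standardized), "repeats": self.repeats,
            "reference": self.reference,
        })


def track_from_sequence(model, seq, frame: Frame, schedule,
                        tie_tol: float = TIE_TOLERANCE_MM, **meta) -> CondylarTrack:
    """Condylar track at each schedule angle of a pose sequence.

    Frames matching a schedule angle exactly are used directly; otherwise
    condylar positions are linearly interpolated in flexion between the two
    bracketing frames, falling back to the nearest frame when only one side
    exists within ``FLEXION_MATCH_WINDOW_DEG``.
    """
    flex = seq.flexion
    cache: dict[int, tuple] = {}

    def positions(i: int):
        if i not in cache:
            cache[i] = condylar_positions(model, seq.frames[i].poses, frame, tie_tol=tie_tol)
        return cache[i]

    rows = []
    for angle in schedule:
        exact = np.flatnonzero(np.isclose(flex, angle, atol=1e-9))
        if exact.size:
            (am, mm_), (al, ml_) = positions(int(exact[0]))
        else:
            above = np.flatnonzero(flex > angle)
            below = np.flatnonzero(flex < angle)
            hi = int(above[np.argmin(flex[above] - angle)]) if above.size else None
            lo = int(below[np.argmin(angle - flex[below])]) if below.size else None
            near = [i for i in (hi, lo)
                    if i is not None and abs(flex[i] - angle) <= FLEXION_MATCH_WINDOW_DEG]
            if hi is not None and lo is not None:
                w = (angle - flex[lo]) / (flex[hi] - flex[lo])
                p_hi, p_lo = np.array(positions(hi)), np.array(positions(lo))
                (am, mm_), (al, ml_) = w * p_hi + (1 - w) * p_lo
            elif len(near) == 1:
                (am, mm_), (al, ml_) = positions(near[0])
            else:
                raise ParameterError(
                    f"no pose frame within {FLEXION_MATCH_WINDOW_DEG} deg of "
                    f"schedule angle {angle} deg")
        rows.append((angle, am, mm_, al, ml_))
    arr = np.array(rows)
    return CondylarTrack(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4], **meta)


def average_repeats(tracks: list[CondylarTrack]) -> CondylarTrack:
    """Coordinate-wise mean of repeated registrations of the same knee."""
    if not tracks:
        raise ParameterError("average_repeats: no tracks given")
    first = tracks[0]
    for t in tracks[1:]:
        if not np.allclose(t.flexion_deg, first.flexion_deg):
            raise ParameterError("average_repeats: mismatched schedules")
        if t.reference != first.reference:
            raise ParameterError("average_repeats: mismatched reference kinds")
        if t.standardized != first.standardized:
            raise ParameterError("average_repeats: mixed standardization")
    return replace(
        first,
        ap_med=np.mean([t.ap_med for t in tracks], axis=0),
        ml_med=np.mean([t.ml_med for t in tracks], axis=0),
        ap_lat=np.mean([t.ap_lat for t in tracks], axis=0),
        ml_lat=np.mean([t.ml_lat for t in tracks], axis=0),
        repeats=len(tracks),
    )


@dataclass(frozen=True)
class StandardizationParams:
    """Scaling of A-P positions to a common reference plateau depth."""

    reference_ap_depth: float = 50.0
    subject_ap_depth: float = 50.0

    def __post_init__(self):
        if self.reference_ap_depth <= 0:
            raise ParameterError("reference_ap_depth must be > 0")
        if self.subject_ap_depth <= 0:
            raise ParameterError("subject_ap_depth must be > 0")


def standardize_ap(track: CondylarTrack, params: StandardizationParams) -> CondylarTrack:
    """Scale A-P coordinates by ``reference/subject`` plateau depth.

    The result is flagged ``standardized`` and is rejected by
    :func:`ie_rotation`: rotation is always computed from raw positions.
    """
    ratio = params.reference_ap_depth / params.subject_ap_depth
    return replace(track, ap_med=track.ap_med * ratio, ap_lat=track.ap_lat * ratio,
                   standardized=True)


def _ml_line_angle(track: CondylarTrack, flexion: float) -> float:
    i = track._index_of(flexion)
    return float(np.degrees(np.arctan2(
        track.ap_med[i] - track.ap_lat[i],
        track.ml_lat[i] - track.ml_med[i])))


def ie_rotation(track: CondylarTrack, flex_a: float, flex_b: float) -> float:
    """I-E rotation between two schedule angles (``theta(a) - theta(b)``).

    ``theta(f)`` is the orientation of the medial-lateral line through the
    two condylar lowest points; positive output is internal tibial rotation
    (lateral femoral condyle posterior relative to medial, right knee).
    Standardized tracks are refused: standardization rescales A-P only and
    would corrupt the angle.
    """
    if track.standardized:
        raise ContractError("ie_rotation requires a non-standardized track")
    return _ml_line_angle(track, flex_a) - _ml_line_angle(track, flex_b)


@dataclass
class RotationProfile:
    """I-E rotation versus flexion, relative to extension, with per-arc deltas."""

    flexion_deg: np.ndarray
    rotation_deg: np.ndarray
    arcs: list[tuple[float, float, float]]  # (flexion_hi, flexion_lo, delta_deg)
    max_flexion_rotation: float
    activity: str | None = None
    knee_id: str | None = None
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "knee_id": self.knee_id, "group": self.group, "activity": self.activity,
            "flexion_deg": self.flexion_deg, "rotation_deg": self.rotation_deg,
        })

    def arcs_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.arcs, columns=["flexion_hi", "flexion_lo", "delta_deg"]) \
            .assign(knee_id=self.knee_id, group=self.group, activity=self.activity)


def build_rotation_profile(track: CondylarTrack, activity: str | None = None) -> RotationProfile:
    """Rotation profile over an activity schedule: rotation at each angle
    relative to full extension, plus the per-arc rotation changes
    (4 arcs of 15 deg for step up, 3 arcs of 30 deg for chair rise)."""
    activity = activity or track.activity
    if activity not in ACTIVITY_SCHEDULES:
        raise ParameterError(f"unknown activity {activity!r}")
    schedule = ACTIVITY_SCHEDULES[activity]
    missing = [a for a in schedule
               if not np.any(np.isclose(track.flexion_deg, a, atol=1e-9))]
    if missing:
        raise ParameterError(f"track missing schedule angles {missing} for {activity}")
    extension = schedule[-1]
    rotation = np.array([ie_rotation(track, a, extension) for a in schedule])
    arcs = [(hi, lo, float(r_hi - r_lo))
            for (hi, r_hi), (lo, r_lo) in zip(zip(schedule, rotation),
                                              zip(schedule[1:], rotation[1:]))]
    return RotationProfile(
        np.array(schedule), rotation, arcs, float(rotation[0]),
        activity=activity, knee_id=track.knee_id, group=track.group)
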