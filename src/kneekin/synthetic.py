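"""Parametric synthetic knees, TKA components and motion trajectories.

Every downstream stage of the pipeline (frame construction, lowest-point
tracking, rotation profiles, cohort statistics) is testable against this
module because each generated model carries an analytic landmark record:
the femoral condyles are spherical caps of known centers and radii, the
medial tibial articular surface is exactly planar, and trajectories come
with the exact imposed rotation per frame (:class:`GroundTruth`).

Geometry convention (right knee, tibia-fixed lab frame): ``+x`` lateral,
``+y`` anterior, ``+z`` proximal; joint line at ``z = 0``; units mm / deg.

The two motion paths emulate the cohort-level patterns of interest:

``screw_home``
    Native-knee pattern: rotation concentrated in the terminal arc of
    extension.  The rotation fraction is ``s(u) = 1 - (1 - u)**4`` of the
    flexion fraction ``u``, which places >= 60% of the total rotation in
    the final schedule arc for both activities.
``progressive``
    Medial-pivot TKA pattern: rotation linear in flexion, with the medial
    condyle's A-P position pinned (ball-in-socket medial conformity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation as _Rot

from ._geom import AP, ML, PD, Line, Plane, rigid_transform, rotation_about, unit
from .errors import ParameterError
from .io import PoseFrame, PoseSequence
from .kinematics import ACTIVITY_SCHEDULES

SCREW_HOME_EXPONENT = 4.0

#: Default medial-condyle posterior shift (mm) at 30 deg flexion relative to
#: extension, per activity, for the native (screw-home) path.
DEFAULT_MEDIAL_SHIFT = {"step_up": 5.1, "chair_rise": 4.5}


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise ParameterError(f"{name}: {message}")


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class KneeSpec:
    """Parametric native-knee geometry.

    Shaft lengths must be at least 130 mm so that the 12 cm anatomic-axis
    level exists on both bones.
    """

    side: str = "right"
    medial_condyle_radius: float = 24.0
    lateral_condyle_radius: float = 22.0
    condyle_ml_separation: float = 46.0
    plateau_ap_depth: float = 50.0
    plateau_ml_width: float = 75.0
    plateau_varus_angle: float = 0.0
    shaft_length_femur: float = 160.0
    shaft_length_tibia: float = 160.0
    mesh_edge_mm: float = 1.0

    def __post_init__(self):
        _require(self.side in ("left", "right"), "side", f"must be left|right, got {self.side!r}")
        _require(self.medial_condyle_radius > 0, "medial_condyle_radius", "must be > 0")
        _require(self.lateral_condyle_radius > 0, "lateral_condyle_radius", "must be > 0")
        _require(self.condyle_ml_separation > 0, "condyle_ml_separation", "must be > 0")
        _require(self.plateau_ap_depth > 0, "plateau_ap_depth", "must be > 0")
        _require(self.plateau_ml_width > 0, "plateau_ml_width", "must be > 0")
        _require(self.shaft_length_femur >= 130, "shaft_length_femur",
                 "must be >= 130 mm (12 cm axis level must exist)")
        _require(self.shaft_length_tibia >= 130, "shaft_length_tibia",
                 "must be >= 130 mm (12 cm axis level must exist)")
        _require(self.mesh_edge_mm > 0, "mesh_edge_mm", "must be > 0")


@dataclass(frozen=True)
class TKASpec(KneeSpec):
    """Knee geometry plus TKA component dimensions.  The femoral component
    has constant-radius condyles (the medial radius is used for both)."""

    baseplate_ap_depth: float = 50.0
    baseplate_ml_width: float = 70.0
    baseplate_thickness: float = 4.0
    insert_type: str = "ball_in_socket_medial_flat_lateral"

    def __post_init__(self):
        super().__post_init__()
        _require(self.baseplate_ap_depth > 0, "baseplate_ap_depth", "must be > 0")
        _require(self.baseplate_ml_width > 0, "baseplate_ml_width", "must be > 0")


@dataclass(frozen=True)
class MotionSpec:
    """An activity trial: flexion schedule, rotation path and magnitude.

    ``medial_posterior_shift_at_30`` defaults by path: the activity value
    (5.1 mm step up / 4.5 mm chair rise) for ``screw_home`` (native) and
    0 mm for ``progressive`` (medial-pivot TKA).
    """

    activity: str = "step_up"
    flexion_schedule: tuple[float, ...] | None = None
    rotation_path: str = "screw_home"
    max_internal_rotation: float = 13.0
    medial_posterior_shift_at_30: float | None = None
    frames_per_arc: int = 10

    def __post_init__(self):
        _require(self.activity in ACTIVITY_SCHEDULES, "activity",
                 f"must be one of {sorted(ACTIVITY_SCHEDULES)}, got {self.activity!r}")
        _require(self.rotation_path in ("screw_home", "progressive"), "rotation_path",
                 f"must be screw_home|progressive, got {self.rotation_path!r}")
        if self.flexion_schedule is None:
            object.__setattr__(self, "flexion_schedule", ACTIVITY_SCHEDULES[self.activity])
        sched = tuple(float(a) for a in self.flexion_schedule)
        object.__setattr__(self, "flexion_schedule", sched)
        _require(all(0 <= a <= 150 for a in sched), "flexion_schedule",
                 "angles must lie in [0, 150] deg")
        _require(all(a > b for a, b in zip(sched, sched[1:])), "flexion_schedule",
                 "must be strictly decreasing")
        _require(np.isfinite(self.max_internal_rotation), "max_internal_rotation",
                 "must be finite")
        if self.medial_posterior_shift_at_30 is None:
            shift = DEFAULT_MEDIAL_SHIFT[self.activity] if self.rotation_path == "screw_home" else 0.0
            object.__setattr__(self, "medial_posterior_shift_at_30", shift)
        _require(self.medial_posterior_shift_at_30 >= 0,
                 "medial_posterior_shift_at_30", "must be >= 0")
        _require(self.frames_per_arc >= 1, "frames_per_arc", "must be >= 1")

    # -- path functions -----------------------------------------------------

    def rotation_at(self, flexion_deg) -> np.ndarray | float:
        """True internal tibial rotation (deg) relative to extension."""
        fmax = self.flexion_schedule[0]
        u = np.clip(np.asarray(flexion_deg, dtype=float) / fmax, 0.0, 1.0)
        if self.rotation_path == "progressive":
            s = u
        else:
            s = 1.0 - (1.0 - u) ** SCREW_HOME_EXPONENT
        return self.max_internal_rotation * s

    def medial_shift_at(self, flexion_deg) -> np.ndarray | float:
        """Medial-condyle A-P offset (mm, negative posterior) vs extension;
        ramps linearly to the full shift at 30 deg and stays there."""
        f = np.asarray(flexion_deg, dtype=float)
        return -self.medial_posterior_shift_at_30 * np.minimum(f, 30.0) / 30.0


@dataclass(frozen=True)
class NoiseSpec:
    """Registration-imprecision model for single-plane fluoroscopy:
    anisotropic translation noise (out-of-plane = medial-lateral axis is
    much worse than in-plane) plus small per-axis rotation noise."""

    sigma_translation_inplane: float = 0.25
    sigma_translation_outofplane: float = 2.0
    sigma_rotation: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_translation_inplane", "sigma_translation_outofplane",
                     "sigma_rotation"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")


@dataclass
class GroundTruth:
    """Exact imposed kinematics per trajectory frame (rotation is zero at
    the extension frame by construction)."""

    flexion_deg: np.ndarray
    ie_deg: np.ndarray
    ap_med_mm: np.ndarray
    ap_lat_mm: np.ndarray

    def at_flexion(self, angle: float) -> dict[str, float]:
        i = int(np.flatnonzero(np.isclose(self.flexion_deg, angle, atol=1e-9))[0])
        return {"flexion_deg": float(self.flexion_deg[i]),
                "ie_deg": float(self.ie_deg[i]),
                "ap_med_mm": float(self.ap_med_mm[i]),
                "ap_lat_mm": float(self.ap_lat_mm[i])}


# ---------------------------------------------------------------------------
# landmark record and models


@dataclass
class Landmarks:
    """Analytic record attached to every generated model; the oracle for
    mesh-derived constructions."""

    medial_condyle_center: np.ndarray
    medial_condyle_radius: float
    lateral_condyle_center: np.ndarray
    lateral_condyle_radius: float
    condylar_axis: Line
    medial_plateau_plane: Plane
    lateral_plateau_plane: Plane
    tibial_medial_center: np.ndarray
    tibial_lateral_center: np.ndarray
    joint_line_z: float = 0.0
    baseplate_center: np.ndarray | None = None
    baseplate_plane: Plane | None = None
    baseplate_ap_depth: float | None = None


@dataclass
class KneeModel:
    """Native knee: bone meshes, condylar/articular submeshes, landmarks."""

    spec: KneeSpec
    femur: trimesh.Trimesh
    tibia: trimesh.Trimesh
    medial_condyle: trimesh.Trimesh
    lateral_condyle: trimesh.Trimesh
    medial_plateau_patch: trimesh.Trimesh
    lateral_plateau_patch: trimesh.Trimesh
    landmarks: Landmarks
    kind: str = "native"
    moving_body: str = "femur"
    fixed_body: str = "tibia"

    @property
    def bodies(self) -> dict[str, trimesh.Trimesh]:
        return {self.moving_body: self.femur, self.fixed_body: self.tibia}


@dataclass
class TKAModel:
    """TKA stand-in: constant-radius femoral component and baseplate."""

    spec: TKASpec
    femoral_component: trimesh.Trimesh
    baseplate: trimesh.Trimesh
    medial_condyle: trimesh.Trimesh
    lateral_condyle: trimesh.Trimesh
    landmarks: Landmarks
    kind: str = "tka"
    moving_body: str = "femoral_component"
    fixed_body: str = "baseplate"

    @property
    def bodies(self) -> dict[str, trimesh.Trimesh]:
        return {self.moving_body: self.femoral_component, self.fixed_body: self.baseplate}


# ---------------------------------------------------------------------------
# mesh builders


def _icosphere(center, radius: float, edge_mm: float) -> trimesh.Trimesh:
    """Icosphere with target edge length, rotated so one original
    icosahedron vertex sits exactly at the distal pole (-z).  The pole
    vertex and its 5-fold-symmetric neighbours make the tie-centroid
    lowest point land on the sphere axis under an identity pose."""
    base_edge = 1.0514622242382672 * radius  # icosahedron edge for unit circumradius
    subdivisions = max(0, int(np.ceil(np.log2(base_edge / edge_mm))))
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    # rotate the vertex nearest -z exactly onto -z
    v = mesh.vertices[np.argmin(mesh.vertices[:, 2])]
    target = np.array([0.0, 0.0, -radius])
    axis = np.cross(v, target)
    if np.linalg.norm(axis) > 1e-12:
        angle = np.arccos(np.clip(np.dot(v, target) / radius**2, -1, 1))
        R = _Rot.from_rotvec(unit(axis) * angle).as_matrix()
        mesh.vertices = mesh.vertices @ R.T
    mesh.vertices = mesh.vertices + np.asarray(center, dtype=float)
    return mesh


def _cylinder(radius: float, z0: float, z1: float, edge_mm: float,
              center_xy=(0.0, 0.0)) -> trimesh.Trimesh:
    sections = int(np.clip(np.ceil(2 * np.pi * radius / edge_mm), 16, 256))
    mesh = trimesh.creation.cylinder(radius=radius, height=z1 - z0, sections=sections)
    mesh.vertices = mesh.vertices + np.array([center_xy[0], center_xy[1], (z0 + z1) / 2.0])
    return mesh


def _hexahedron(x0, x1, y0, y1, z_bottom, z_top_at) -> trimesh.Trimesh:
    """Closed 8-vertex block; ``z_top_at(x)`` gives the (possibly tilted)
    top-surface height."""
    corners = np.array([
        [x0, y0, z_bottom], [x1, y0, z_bottom], [x1, y1, z_bottom], [x0, y1, z_bottom],
        [x0, y0, z_top_at(x0)], [x1, y0, z_top_at(x1)],
        [x1, y1, z_top_at(x1)], [x0, y1, z_top_at(x0)],
    ])
    faces = np.array([
        [0, 2, 1], [0, 3, 2],          # bottom (normal -z)
        [4, 5, 6], [4, 6, 7],          # top
        [0, 1, 5], [0, 5, 4],          # y0 side
        [2, 3, 7], [2, 7, 6],          # y1 side
        [1, 2, 6], [1, 6, 5],          # x1 side
        [3, 0, 4], [3, 4, 7],          # x0 side
    ])
    return trimesh.Trimesh(vertices=corners, faces=faces, process=False)


def _surface_grid(x0, x1, y0, y1, z_at, step: float = 5.0) -> trimesh.Trimesh:
    """Triangulated rectangular surface patch with height ``z_at(x)``."""
    nx = max(2, int(np.ceil((x1 - x0) / step)) + 1)
    ny = max(2, int(np.ceil((y1 - y0) / step)) + 1)
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), z_at(X.ravel())])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = i * ny + j, (i + 1) * ny + j, (i + 1) * ny + j + 1, i * ny + j + 1
            faces += [[a, b, c], [a, c, d]]
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _mirror_ml(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    out = mesh.copy()
    out.vertices = out.vertices * np.array([-1.0, 1.0, 1.0])
    out.faces = out.faces[:, ::-1]
    return out


def _mirror_point(p):
    return np.asarray(p, float) * np.array([-1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# model generation


def generate_knee_model(spec: KneeSpec = KneeSpec()) -> KneeModel:
    """Build a native knee in right-knee convention (left specs are the
    mirrored right model).

    Femoral condyles are spheres tangent to the medial plateau plane
    (z = 0); the medial tibial articular surface is exactly planar and the
    lateral surface is tilted by ``plateau_varus_angle`` about the A-P axis
    through the plateau midline (positive angle -> lateral side lower).
    """
    s = spec
    d = s.condyle_ml_separation
    edge = s.mesh_edge_mm
    c_med = np.array([-d / 2.0, 0.0, s.medial_condyle_radius])
    c_lat = np.array([+d / 2.0, 0.0, s.lateral_condyle_radius])

    medial_condyle = _icosphere(c_med, s.medial_condyle_radius, edge)
    lateral_condyle = _icosphere(c_lat, s.lateral_condyle_radius, edge)
    shaft_f = _cylinder(13.0, 30.0, s.shaft_length_femur, edge)
    femur = trimesh.util.concatenate([medial_condyle, lateral_condyle, shaft_f])

    w, ap = s.plateau_ml_width, s.plateau_ap_depth
    tanv = np.tan(np.radians(s.plateau_varus_angle))
    slab_bottom = -20.0
    medial_block = _hexahedron(-w / 2, 0.0, -ap / 2, ap / 2, slab_bottom, lambda x: 0.0 * x)
    # lateral block overlaps the medial by 1 mm: coincident internal walls
    # would make plane-section contour reconstruction ambiguous
    lateral_block = _hexahedron(-1.0, w / 2, -ap / 2, ap / 2, slab_bottom,
                                lambda x: -np.asarray(x) * tanv)
    shaft_t = _cylinder(12.0, -s.shaft_length_tibia, slab_bottom + 2.0, edge)
    tibia = trimesh.util.concatenate([medial_block, lateral_block, shaft_t])

    medial_patch = _surface_grid(-w / 2, 0.0, -ap / 2, ap / 2, lambda x: 0.0 * x)
    lateral_patch = _surface_grid(0.0, w / 2, -ap / 2, ap / 2,
                                  lambda x: -np.asarray(x) * tanv)

    lat_normal = unit(np.array([np.sin(np.radians(s.plateau_varus_angle)), 0.0,
                                np.cos(np.radians(s.plateau_varus_angle))]))
    landmarks = Landmarks(
        medial_condyle_center=c_med, medial_condyle_radius=s.medial_condyle_radius,
        lateral_condyle_center=c_lat, lateral_condyle_radius=s.lateral_condyle_radius,
        condylar_axis=Line(c_med, c_lat - c_med),
        medial_plateau_plane=Plane(np.array([-w / 4, 0.0, 0.0]), PD),
        lateral_plateau_plane=Plane(np.array([w / 4, 0.0, -(w / 4) * tanv]), lat_normal),
        tibial_medial_center=np.array([-w / 4, 0.0, 0.0]),
        tibial_lateral_center=np.array([w / 4, 0.0, -(w / 4) * tanv]),
    )
    model = KneeModel(spec=s, femur=femur, tibia=tibia,
                      medial_condyle=medial_condyle, lateral_condyle=lateral_condyle,
                      medial_plateau_patch=medial_patch, lateral_plateau_patch=lateral_patch,
                      landmarks=landmarks)
    if s.side == "left":
        model = _mirror_model(model)
    return model


def _mirror_model(model):
    lm = model.landmarks
    mirrored_lm = replace(
        lm,
        medial_condyle_center=_mirror_point(lm.medial_condyle_center),
        lateral_condyle_center=_mirror_point(lm.lateral_condyle_center),
        condylar_axis=Line(_mirror_point(lm.condylar_axis.point),
                           _mirror_point(lm.condylar_axis.direction)),
        medial_plateau_plane=Plane(_mirror_point(lm.medial_plateau_plane.point),
                                   _mirror_point(lm.medial_plateau_plane.normal)),
        lateral_plateau_plane=Plane(_mirror_point(lm.lateral_plateau_plane.point),
                                    _mirror_point(lm.lateral_plateau_plane.normal)),
        tibial_medial_center=_mirror_point(lm.tibial_medial_center),
        tibial_lateral_center=_mirror_point(lm.tibial_lateral_center),
        baseplate_center=(None if lm.baseplate_center is None
                          else _mirror_point(lm.baseplate_center)),
        baseplate_plane=(None if lm.baseplate_plane is None
                         else Plane(_mirror_point(lm.baseplate_plane.point),
                                    _mirror_point(lm.baseplate_plane.normal))),
    )
    kwargs = {f.name: getattr(model, f.name) for f in fields(model)}
    for name, value in kwargs.items():
        if isinstance(value, trimesh.Trimesh):
            kwargs[name] = _mirror_ml(value)
    kwargs["landmarks"] = mirrored_lm
    return type(model)(**kwargs)


def generate_tka_model(spec: TKASpec = TKASpec()) -> TKAModel:
    """Constant-radius femoral component (two equal-radius spherical
    condyles bridged by a box) over a rectangular baseplate whose top
    surface lies at z = 0 and whose A-P extent is exactly
    ``baseplate_ap_depth``."""
    s = spec
    r = s.medial_condyle_radius
    d = s.condyle_ml_separation
    edge = s.mesh_edge_mm
    c_med = np.array([-d / 2.0, 0.0, r])
    c_lat = np.array([+d / 2.0, 0.0, r])
    medial_condyle = _icosphere(c_med, r, edge)
    lateral_condyle = _icosphere(c_lat, r, edge)
    bridge = trimesh.creation.box(extents=[d, r, 10.0])
    bridge.vertices = bridge.vertices + np.array([0.0, 0.0, r + 10.0])
    component = trimesh.util.concatenate([medial_condyle, lateral_condyle, bridge])

    plate = trimesh.creation.box(
        extents=[s.baseplate_ml_width, s.baseplate_ap_depth, s.baseplate_thickness])
    plate_center = np.array([0.0, 0.0, -s.baseplate_thickness / 2.0])
    plate.vertices = plate.vertices + plate_center

    landmarks = Landmarks(
        medial_condyle_center=c_med, medial_condyle_radius=r,
        lateral_condyle_center=c_lat, lateral_condyle_radius=r,
        condylar_axis=Line(c_med, c_lat - c_med),
        medial_plateau_plane=Plane(np.zeros(3), PD),
        lateral_plateau_plane=Plane(np.zeros(3), PD),
        tibial_medial_center=np.array([-s.baseplate_ml_width / 4, 0.0, 0.0]),
        tibial_lateral_center=np.array([s.baseplate_ml_width / 4, 0.0, 0.0]),
        baseplate_center=plate_center,
        baseplate_plane=Plane(np.zeros(3), PD),
        baseplate_ap_depth=s.baseplate_ap_depth,
    )
    model = TKAModel(spec=s, femoral_component=component, baseplate=plate,
                     medial_condyle=medial_condyle, lateral_condyle=lateral_condyle,
                     landmarks=landmarks)
    if s.side == "left":
        model = _mirror_model(model)
    return model


# ---------------------------------------------------------------------------
# trajectories


def _flexion_samples(motion: MotionSpec, frames: int | None) -> np.ndarray:
    sched = np.array(motion.flexion_schedule)
    if frames is None:
        parts = [np.linspace(hi, lo, motion.frames_per_arc + 1)[:-1]
                 for hi, lo in zip(sched, sched[1:])]
        return np.concatenate(parts + [sched[-1:]])
    if frames < len(sched):
        raise ParameterError(
            f"frames={frames} < number of schedule angles ({len(sched)})")
    dense = np.linspace(sched[0], sched[-1], frames)
    merged = np.concatenate([dense, sched])
    merged = np.unique(np.round(merged, 9))[::-1]
    # keep exact schedule floats (np.round is only used for dedup)
    for a in sched:
        merged[np.isclose(merged, a, atol=1e-9)] = a
    return merged


def generate_trajectory(model, motion: MotionSpec,
                        frames: int | None = None) -> tuple[PoseSequence, GroundTruth]:
    """Femoral pose per flexion sample plus the exact imposed kinematics.

    Per frame with flexion ``f``: the femur is flexed by ``f`` about the
    trans-condylar axis (through both condyle centers, so the centers stay
    put), internally rotated by the path rotation ``rho(f)`` about the
    proximal-distal axis through the *medial* condyle center (medial
    pivot), and translated anteriorly by the medial-shift offset.  The
    tibia stays at identity.  Ground truth records ``rho(f)`` and the
    condyle-center A-P positions.
    """
    lm = model.landmarks
    flex = _flexion_samples(motion, frames)
    d_ml = np.linalg.norm((lm.lateral_condyle_center - lm.medial_condyle_center)[:2])
    sign_ml = 1.0 if (lm.lateral_condyle_center - lm.medial_condyle_center)[0] >= 0 else -1.0

    pose_frames = []
    rho = np.asarray(motion.rotation_at(flex), dtype=float)
    shift = np.asarray(motion.medial_shift_at(flex), dtype=float)
    for i, f in enumerate(flex):
        t_flex = rotation_about(lm.condylar_axis.point, lm.condylar_axis.direction, f)
        t_rot = rotation_about(lm.medial_condyle_center, PD, -sign_ml * rho[i])
        t_shift = rigid_transform(translation=shift[i] * AP)
        pose = t_shift @ t_rot @ t_flex
        pose_frames.append(PoseFrame(i, float(f), {
            model.moving_body: pose, model.fixed_body: np.eye(4)}))

    truth = GroundTruth(
        flexion_deg=flex,
        ie_deg=rho,
        ap_med_mm=shift + lm.medial_condyle_center[1],
        ap_lat_mm=shift + lm.medial_condyle_center[1]
        - d_ml * np.sin(np.radians(rho)),
    )
    return PoseSequence(pose_frames), truth


def apply_registration_noise(seq: PoseSequence, noise: NoiseSpec) -> PoseSequence:
    """Independently perturb every body pose in every frame.

    Translation noise is zero-mean Gaussian per axis with the in-plane
    sigma on the A-P and proximal-distal axes and the out-of-plane sigma
    on the medial-lateral axis (single-plane fluoroscopy views the knee
    roughly along ML).  Rotation noise is a rotation vector with
    independent zero-mean per-axis components of SD ``sigma_rotation``
    degrees, applied about the body's own position.  Deterministic under
    ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    sig_t = np.array([noise.sigma_translation_outofplane,
                      noise.sigma_translation_inplane,
                      noise.sigma_translation_inplane])
    out_frames = []
    for frame in seq.frames:
        poses = {}
        for body in sorted(frame.poses):
            T = frame.poses[body].copy()
            dt = rng.normal(0.0, 1.0, 3) * sig_t
            rotvec = np.radians(rng.normal(0.0, noise.sigma_rotation, 3))
            dR = _Rot.from_rotvec(rotvec).as_matrix()
            p = T[:3, 3]
            T[:3, :3] = dR @ T[:3, :3]
            T[:3, 3] = dR @ (T[:3, 3] - p) + p + dt
            poses[body] = T
        out_frames.append(PoseFrame(frame.index, frame.flexion_deg, poses))
    return PoseSequence(out_frames)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortMember:
    knee_id: str
    group: str
    model: KneeModel | TKAModel
    motion: MotionSpec
    sequence: PoseSequence
    repeats: list[PoseSequence]
    truth: GroundTruth


def generate_cohort(n_per_group: int,
                    spec: KneeSpec | TKASpec = KneeSpec(),
                    motion: MotionSpec = MotionSpec(),
                    rotation_mean: float = 13.0,
                    rotation_sd: float = 4.6,
                    geometry_cv: float = 0.0,
                    noise: NoiseSpec | None = None,
                    n_repeats: int = 3,
                    seed: int = 0,
                    group: str = "native") -> list[CohortMember]:
    """A group of knees with per-knee variation of maximum rotation
    (normal, ``rotation_mean`` +/- ``rotation_sd``) and optional overall
    geometric scale variation (``geometry_cv``).  With registration noise
    enabled, each knee carries ``n_repeats`` independently perturbed pose
    sequences emulating repeated registrations.  Reproducible under
    ``seed``."""
    if n_per_group < 2:
        raise ParameterError(f"n_per_group must be >= 2, got {n_per_group}")
    rng = np.random.default_rng(seed)
    is_tka = isinstance(spec, TKASpec)
    shared_model = None
    if geometry_cv == 0.0:
        shared_model = generate_tka_model(spec) if is_tka else generate_knee_model(spec)

    members = []
    for k in range(n_per_group):
        max_rot = float(rng.normal(rotation_mean, rotation_sd))
        if geometry_cv == 0.0:
            model = shared_model
        else:
            scale = float(np.clip(rng.normal(1.0, geometry_cv), 0.6, 1.4))
            scaled = replace(
                spec,
                medial_condyle_radius=spec.medial_condyle_radius * scale,
                lateral_condyle_radius=spec.lateral_condyle_radius * scale,
                condyle_ml_separation=spec.condyle_ml_separation * scale,
                plateau_ap_depth=spec.plateau_ap_depth * scale,
                plateau_ml_width=spec.plateau_ml_width * scale,
            )
            model = generate_tka_model(scaled) if is_tka else generate_knee_model(scaled)
        knee_motion = replace(motion, max_internal_rotation=max_rot)
        seq, truth = generate_trajectory(model, knee_motion)
        if noise is None:
            repeats = [seq]
        else:
            n_rep = 1 if is_tka else n_repeats
            repeats = [
                apply_registration_noise(
                    seq, replace(noise, seed=int(rng.integers(0, 2**31 - 1))))
                for _ in range(n_rep)
            ]
        members.append(CohortMember(
            knee_id=f"{group}_{k:03d}", group=group, model=model,
            motion=knee_motion, sequence=seq, repeats=repeats, truth=truth))
    return members
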