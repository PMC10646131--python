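"""Anatomic axes, flexion angle, reference planes and tibial frames.

All constructions operate on triangulated surface meshes and follow the
measurement chain used for weight-bearing fluoroscopic knee studies:

* anatomic axes join the cross-section midpoints at two shaft levels
  (7/12 cm above the joint line for the femur, 5/12 cm below for the
  tibia); flexion is the supplement of the included axis angle, so a
  straight limb reads 0 deg;
* the femoral sagittal plane normal joins the best-fit sphere centers of
  the posterior condylar surfaces;
* the axial plane is the medial tibial articular plane re-orthogonalized
  (about A-P only) to be perpendicular to the sagittal plane;
* the simulated tibial resection plane is that plane shifted 10 mm
  distally from the medial tibial condyle center, varus-valgus adjusted
  in 2 deg increments until the medial and lateral condylar thicknesses
  agree within +/- 0.5 mm;
* the tibial frame origin is the center of the bounding box of the
  tibial contour in the resection plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import PD, Frame, Line, Plane, angle_between_deg, fit_plane, fit_sphere, \
    rotation_matrix, unit
from .errors import ConvergenceError, GeometryError, ParameterError

#: Shaft levels (mm from the joint line) defining the anatomic axes.
FEMUR_AXIS_LEVELS = (70.0, 120.0)
TIBIA_AXIS_LEVELS = (50.0, 120.0)


# ---------------------------------------------------------------------------
# cross-sections and anatomic axes


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = unit(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(n, helper))
    e2 = np.cross(n, e1)
    return e1, e2


def _polygon_area_centroid(pts2: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed shoelace area and area centroid of a closed 2D polygon
    (first point not repeated)."""
    x, y = pts2[:, 0], pts2[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        return 0.0, pts2.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(area), np.array([cx, cy])


def cross_section_midpoint(mesh, level_plane: Plane) -> np.ndarray:
    """Area centroid of the largest closed contour where ``level_plane``
    intersects the mesh; a point on the plane."""
    section = mesh.section(plane_origin=level_plane.point,
                           plane_normal=level_plane.normal)
    if section is None:
        raise GeometryError("cross-section plane does not intersect the mesh")
    e1, e2 = _plane_basis(level_plane.normal)
    best = None
    n_closed = 0
    for poly in section.discrete:
        closed = np.allclose(poly[0], poly[-1], atol=1e-8)
        if not closed:
            continue
        n_closed += 1
        pts2 = (poly[:-1] - level_plane.point) @ np.column_stack([e1, e2])
        area, centroid = _polygon_area_centroid(pts2)
        if best is None or abs(area) > abs(best[0]):
            best = (area, centroid)
    if n_closed == 0:
        raise GeometryError("cross-section contour is open")
    centroid3 = level_plane.point + best[1][0] * e1 + best[1][1] * e2
    return centroid3


def anatomic_axis(mesh, joint_line_z: float, levels: tuple[float, float],
                  toward: str = "proximal") -> Line:
    """Line through the shaft cross-section midpoints at two levels from
    the joint line, directed away from the joint.

    ``toward='proximal'`` measures levels above the joint line (femur);
    ``'distal'`` below (tibia).
    """
    if toward not in ("proximal", "distal"):
        raise ParameterError(f"toward must be proximal|distal, got {toward!r}")
    lv_near, lv_far = float(levels[0]), float(levels[1])
    if np.isclose(lv_near, lv_far):
        raise ParameterError(f"axis levels must be distinct, got {levels}")
    if lv_near <= 0 or lv_far <= 0:
        raise ParameterError(f"axis levels must be positive, got {levels}")
    sign = 1.0 if toward == "proximal" else -1.0
    zmin, zmax = mesh.bounds[:, 2]
    mids = []
    for lv in (lv_near, lv_far):
        z = joint_line_z + sign * lv
        if not (zmin - 1e-9 <= z <= zmax + 1e-9):
            raise GeometryError(
                f"axis level {lv} mm ({toward}) at z={z:.1f} lies outside the "
                f"bone extent [{zmin:.1f}, {zmax:.1f}]")
        mids.append(cross_section_midpoint(mesh, Plane([0, 0, z], PD)))
    near, far = (mids[0], mids[1]) if lv_near < lv_far else (mids[1], mids[0])
    return Line(near, far - near)


def flexion_angle(femur_axis, tibia_axis) -> float:
    """Knee flexion (deg) from the two anatomic axes, each directed away
    from the joint: 180 deg minus their included angle, so a straight limb
    reads 0 and a right-angle knee reads 90.  Symmetric in its arguments
    and invariant to axis scaling."""
    u = femur_axis.direction if isinstance(femur_axis, Line) else np.asarray(femur_axis, float)
    v = tibia_axis.direction if isinstance(tibia_axis, Line) else np.asarray(tibia_axis, float)
    return 180.0 - angle_between_deg(u, v)


# ---------------------------------------------------------------------------
# femoral sagittal frame


def femoral_sagittal_frame(medial_condyle, lateral_condyle,
                           proximal_hint: np.ndarray = PD,
                           posterior_hint: np.ndarray | None = None,
                           fit_rms_tol: float = 1.0,
                           min_vertices: int = 50) -> Frame:
    """Frame whose sagittal-plane normal (the ML axis) joins the best-fit
    sphere centers of the two posterior condylar surfaces.

    The posterior surface of each condyle is taken as the most-posterior
    25% of its vertices (along ``-posterior_hint``, default lab -AP).
    Raises :class:`GeometryError` for patches under ``min_vertices``
    vertices or sphere-fit RMS above ``fit_rms_tol`` mm.
    """
    post = unit(posterior_hint) if posterior_hint is not None else np.array([0.0, -1.0, 0.0])
    centers, radii = [], []
    for name, condyle in (("medial", medial_condyle), ("lateral", lateral_condyle)):
        verts = np.asarray(getattr(condyle, "vertices", condyle), dtype=float)
        depth = verts @ post
        patch = verts[depth >= np.quantile(depth, 0.75)]
        if len(patch) < min_vertices:
            raise GeometryError(
                f"{name} posterior condylar patch has {len(patch)} vertices "
                f"(< {min_vertices})")
        center, radius, rms = fit_sphere(patch)
        if rms > fit_rms_tol:
            raise GeometryError(
                f"{name} posterior condyle sphere fit RMS {rms:.2f} mm "
                f"exceeds {fit_rms_tol} mm")
        centers.append(center)
        radii.append(radius)
    ml = unit(centers[1] - centers[0])
    pd_axis = unit(proximal_hint - (proximal_hint @ ml) * ml)
    ap_axis = np.cross(pd_axis, ml)
    origin = 0.5 * (centers[0] + centers[1])
    return Frame(origin, ml, ap_axis, pd_axis,
                 meta={"condyle_centers": centers, "condyle_radii": radii})


# ---------------------------------------------------------------------------
# medial plateau plane and simulated resection


def medial_plateau_plane(patch, sagittal: Frame | None = None,
                         proximal_hint: np.ndarray = PD) -> Plane:
    """Least-squares plane of the medial articular patch, normal oriented
    proximally.  With a sagittal frame, the normal is re-orthogonalized to
    be perpendicular to the sagittal-plane normal by a rotation about the
    A-P direction only (its A-P component is preserved)."""
    verts = np.asarray(getattr(patch, "vertices", patch), dtype=float)
    plane = fit_plane(verts)
    n = plane.normal if plane.normal @ unit(proximal_hint) >= 0 else -plane.normal
    if sagittal is not None:
        n_ap = float(n @ sagittal.ap)
        if abs(n_ap) >= 1.0 - 1e-12:
            raise GeometryError("plateau normal parallel to the A-P axis")
        n = n_ap * sagittal.ap + np.sqrt(1.0 - n_ap**2) * np.sign(n @ sagittal.pd + 1e-30) * sagittal.pd
        n = unit(n)
    return Plane(plane.point, n)


@dataclass(frozen=True)
class ResectionParams:
    """Simulated-resection parameters: 10 mm distal offset from the medial
    condyle center, varus-valgus balancing in 2 deg increments to a
    +/- 0.5 mm condylar-thickness tolerance, search bounded at +/- 10 deg."""

    distal_offset: float = 10.0
    vv_increment: float = 2.0
    thickness_tolerance: float = 0.5
    vv_search_limit: float = 10.0

    def __post_init__(self):
        if self.distal_offset <= 0:
            raise ParameterError("distal_offset must be > 0")
        if self.vv_increment <= 0:
            raise ParameterError("vv_increment must be > 0")
        if self.thickness_tolerance <= 0:
            raise ParameterError("thickness_tolerance must be > 0")
        if self.vv_search_limit < 0:
            raise ParameterError("vv_search_limit must be >= 0")


@dataclass(frozen=True)
class ResectionPlane:
    """A balanced simulated tibial resection."""

    plane: Plane
    vv_adjustment_deg: float
    thickness_medial: float
    thickness_lateral: float

    @property
    def imbalance(self) -> float:
        return abs(self.thickness_medial - self.thickness_lateral)


def vv_candidate_angles(params: ResectionParams) -> list[float]:
    """Search order 0, +i, -i, +2i, -2i, ... up to the limit
    (nearest-to-neutral first)."""
    angles = [0.0]
    k = 1
    while k * params.vv_increment <= params.vv_search_limit + 1e-9:
        angles += [k * params.vv_increment, -k * params.vv_increment]
        k += 1
    return angles


def simulate_resection_plane(medial_plane: Plane,
                             medial_center: np.ndarray,
                             lateral_center: np.ndarray,
                             ap_axis: np.ndarray,
                             params: ResectionParams = ResectionParams()) -> ResectionPlane:
    """Balance the simulated tibial resection plane.

    The starting plane is parallel to the medial articular plane, offset
    ``distal_offset`` mm distally from the medial tibial condyle center.
    Candidate varus-valgus adjustments (whole increments, nearest-neutral
    first) tilt the plane normal about the A-P axis through the offset
    point; positive adjustment tilts the normal laterally.  The first
    candidate for which the medial and lateral condylar thicknesses
    (3D point-to-plane distances from the condyle centers) agree within
    ``thickness_tolerance`` wins.
    """
    medial_center = np.asarray(medial_center, dtype=float)
    lateral_center = np.asarray(lateral_center, dtype=float)
    n0 = medial_plane.normal
    p0 = medial_center - params.distal_offset * n0
    best: tuple[float, float] | None = None
    for theta in vv_candidate_angles(params):
        n = rotation_matrix(ap_axis, theta) @ n0
        t_med = abs(float((medial_center - p0) @ n))
        t_lat = abs(float((lateral_center - p0) @ n))
        imbalance = abs(t_med - t_lat)
        if imbalance <= params.thickness_tolerance:
            result = ResectionPlane(Plane(p0, n), theta, t_med, t_lat)
            assert result.imbalance <= params.thickness_tolerance
            return result
        if best is None or imbalance < best[1]:
            best = (theta, imbalance)
    raise ConvergenceError(
        f"no varus-valgus adjustment within +/-{params.vv_search_limit} deg "
        f"balances condylar thicknesses to +/-{params.thickness_tolerance} mm "
        f"(best imbalance {best[1]:.2f} mm at {best[0]:+.0f} deg)",
        best_imbalance_mm=best[1])


# ---------------------------------------------------------------------------
# tibial frames


def tibial_frame(resection: ResectionPlane, tibia, sagittal: Frame) -> Frame:
    """Tibial coordinate system on the simulated resection.

    The origin is the center of the bounding box (axes aligned with the
    sagittal frame's ML/AP directions projected into the resection plane)
    of the tibial contour in the plane; the A-P box extent is recorded as
    the native plateau A-P dimension used for standardization.
    """
    plane = resection.plane
    section = tibia.section(plane_origin=plane.point, plane_normal=plane.normal)
    if section is None:
        raise GeometryError("resection plane does not intersect the tibia")
    closed = [poly for poly in section.discrete
              if np.allclose(poly[0], poly[-1], atol=1e-8)]
    if not closed:
        raise GeometryError("tibial resection contour is open")
    pts = np.vstack([poly[:-1] for poly in closed])
    n = plane.normal
    ml_dir = unit(sagittal.ml - (sagittal.ml @ n) * n)
    ap_dir = np.cross(n, ml_dir)
    u = (pts - plane.point) @ ml_dir
    v = (pts - plane.point) @ ap_dir
    origin = plane.point + 0.5 * (u.max() + u.min()) * ml_dir \
        + 0.5 * (v.max() + v.min()) * ap_dir
    return Frame(origin, ml_dir, ap_dir, n,
                 meta={"ap_depth": float(v.max() - v.min()),
                       "ml_width": float(u.max() - u.min()),
                       "vv_adjustment_deg": resection.vv_adjustment_deg,
                       "reference": "native_resection_plane"})


def baseplate_frame(tka_model) -> Frame:
    """TKA reference frame: origin at the baseplate bounding-box center
    (projected to the plate's top plane for the lowest-point reference),
    ML/AP axes along the plate edges, A-P extent of the box recorded for
    standardization."""
    plate = tka_model.baseplate
    lo, hi = plate.bounds
    center = 0.5 * (lo + hi)
    top = tka_model.landmarks.baseplate_plane
    origin = center + (float((top.point - center) @ top.normal)) * top.normal
    ml_dir = unit(np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ top.normal) * top.normal)
    ap_dir = np.cross(top.normal, ml_dir)
    return Frame(origin, ml_dir, ap_dir, top.normal,
                 meta={"ap_depth": float(hi[1] - lo[1]),
                       "ml_width": float(hi[0] - lo[0]),
                       "reference": "tka_baseplate_bbox"})
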