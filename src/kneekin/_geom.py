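"""Shared geometric primitives: planes, rigid transforms, sphere fits.

Conventions used throughout the package (right-knee, tibia-fixed lab frame):

* ``+x`` lateral (ML), ``+y`` anterior (AP), ``+z`` proximal (PD);
  the triad is right-handed (ML x AP = PD).
* All lengths are millimetres, all angles degrees.
* A pose is a 4x4 homogeneous matrix mapping body-local coordinates into
  the lab frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError

# Lab-frame axis conventions (right knee).
ML = np.array([1.0, 0.0, 0.0])  # +lateral
AP = np.array([0.0, 1.0, 0.0])  # +anterior
PD = np.array([0.0, 0.0, 1.0])  # +proximal


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ParameterError("zero-length vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of ``points`` (n,3) to the plane, positive on
        the side the normal points to."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        return d if np.asarray(points).ndim > 1 else float(d[0])

    def transformed(self, matrix: np.ndarray) -> "Plane":
        m = np.asarray(matrix, dtype=float)
        return Plane(m[:3, :3] @ self.point + m[:3, 3], m[:3, :3] @ self.normal)


@dataclass(frozen=True)
class Line:
    """A directed line (point + unit direction)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", unit(self.direction))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation about ``axis`` (through the origin) by ``angle_deg``."""
    a = unit(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(a, a)


def rigid_transform(
    rotation: np.ndarray | None = None, translation: np.ndarray | None = None
) -> np.ndarray:
    T = np.eye(4)
    if rotation is not None:
        T[:3, :3] = rotation
    if translation is not None:
        T[:3, 3] = np.asarray(translation, dtype=float)
    return T


def rotation_about(point: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """4x4 rigid transform rotating about the axis through ``point``."""
    R = rotation_matrix(axis, angle_deg)
    p = np.asarray(point, dtype=float)
    return rigid_transform(R, p - R @ p)


def transform_points(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return pts @ matrix[:3, :3].T + matrix[:3, 3]


def is_rigid(matrix: np.ndarray, tol: float = 1e-6) -> bool:
    R = np.asarray(matrix, dtype=float)[:3, :3]
    return (
        np.allclose(R @ R.T, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < max(tol, 1e-9)
    )


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Included angle between two directions, in [0, 180] degrees.
    Invariant to the (positive) scaling of either argument."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ParameterError("angle undefined for a zero-length axis")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Solves ``|p|^2 = 2 c.p + (r^2 - |c|^2)`` as a linear system.

    Returns
    -------
    center : (3,) ndarray
    radius : float
    rms : float
        RMS radial residual of the fit, mm.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise GeometryError(f"sphere fit needs >= 4 points, got {pts.shape[0]}")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise GeometryError("sphere fit degenerate (non-positive radius)")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through a point cloud (SVD on the
    centred coordinates; the normal is the smallest singular direction)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise GeometryError("plane fit needs >= 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("plane fit degenerate: points are collinear")
    return Plane(centroid, vt[2])


@dataclass(frozen=True)
class Frame:
    """A right-handed orthonormal anatomical frame (ML, AP, PD axes)."""

    origin: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    pd: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        for name in ("ml", "ap", "pd"):
            object.__setattr__(self, name, unit(getattr(self, name)))
        R = np.column_stack([self.ml, self.ap, self.pd])
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("frame axes are left-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        R = np.column_stack([self.ml, self.ap, self.pd])
        out = pts @ R
        return out if np.asarray(points).ndim > 1 else out[0]

    def translated(self, offset: np.ndarray) -> "Frame":
        return Frame(self.origin + np.asarray(offset, float), self.ml, self.ap, self.pd, dict(self.meta))
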