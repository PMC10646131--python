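"""File formats and containers for meshes, rigid pose sequences, tracks.

Pose CSV schema (one row per body per frame, header required)::

    frame_index,body,flexion_deg,r11,r12,r13,r21,r22,r23,r31,r32,r33,tx,ty,tz

``r11..r33`` is the row-major 3x3 rotation and ``tx,ty,tz`` the translation
(mm) of the homogeneous transform mapping body-local coordinates into the
lab frame.  Rotations must be orthonormal (1e-6) with determinant +1;
reflections are rejected.  ``flexion_deg`` may be empty, in which case the
analysis recomputes it from the anatomic axes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError

POSE_COLUMNS = [
    "frame_index", "body", "flexion_deg",
    "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
    "tx", "ty", "tz",
]

KNOWN_BODIES = {"femur", "tibia", "femoral_component", "baseplate"}


@dataclass
class PoseFrame:
    """Rigid poses of every tracked body at one sampled instant."""

    index: int
    flexion_deg: float
    poses: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "PoseFrame":
        return PoseFrame(self.index, self.flexion_deg,
                         {k: v.copy() for k, v in self.poses.items()})


@dataclass
class PoseSequence:
    """An ordered sequence of :class:`PoseFrame`, the in-memory stand-in
    for the output of a model-to-image registration run."""

    frames: list[PoseFrame]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def bodies(self) -> list[str]:
        return sorted(self.frames[0].poses) if self.frames else []

    @property
    def flexion(self) -> np.ndarray:
        return np.array([f.flexion_deg for f in self.frames])

    def copy(self) -> "PoseSequence":
        return PoseSequence([f.copy() for f in self.frames])


def _validate_rotation(R: np.ndarray, where: str) -> None:
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise FormatError(f"non-orthonormal rotation at {where}")
    if np.linalg.det(R) < 0:
        raise FormatError(f"rotation with determinant -1 (reflection) at {where}")


# ---------------------------------------------------------------------------
# meshes

_MESH_EXTENSIONS = {".stl", ".ply"}


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an STL (ASCII or binary) or PLY surface mesh, vertices in mm."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise FormatError(f"unsupported mesh extension {path.suffix!r}: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # trimesh raises a mix of types on corrupt input
        raise FormatError(f"could not parse mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise FormatError(f"no triangulated geometry in {path}")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise FormatError(f"unsupported mesh extension {path.suffix!r}: {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))


# ---------------------------------------------------------------------------
# pose sequences


def write_poses(seq: PoseSequence, path: str | Path) -> None:
    rows = []
    for frame in seq.frames:
        for body in sorted(frame.poses):
            T = frame.poses[body]
            R, t = T[:3, :3], T[:3, 3]
            rows.append({
                "frame_index": frame.index,
                "body": body,
                "flexion_deg": frame.flexion_deg,
                **{f"r{i + 1}{j + 1}": R[i, j] for i in range(3) for j in range(3)},
                "tx": t[0], "ty": t[1], "tz": t[2],
            })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(path, index=False)


def read_poses(path: str | Path) -> PoseSequence:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"pose file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"could not parse pose CSV {path}: {exc}") from exc
    missing = [c for c in POSE_COLUMNS if c != "flexion_deg" and c not in df.columns]
    if missing:
        raise FormatError(f"pose CSV {path} missing columns: {missing}")
    frames: dict[int, PoseFrame] = {}
    for _, row in df.iterrows():
        idx = int(row["frame_index"])
        R = np.array([[row[f"r{i + 1}{j + 1}"] for j in range(3)] for i in range(3)])
        _validate_rotation(R, f"frame {idx} body {row['body']}")
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = [row["tx"], row["ty"], row["tz"]]
        flex = float(row["flexion_deg"]) if "flexion_deg" in df.columns else np.nan
        frame = frames.setdefault(idx, PoseFrame(idx, flex, {}))
        frame.poses[str(row["body"])] = T
    return PoseSequence([frames[i] for i in sorted(frames)])


# ---------------------------------------------------------------------------
# ground-truth sidecar (written by the synthetic generator)

TRUTH_COLUMNS = ["frame", "flexion_deg", "true_ie_deg", "true_ap_med_mm", "true_ap_lat_mm"]


def write_ground_truth(truth, path: str | Path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(truth.flexion_deg)),
        "flexion_deg": truth.flexion_deg,
        "true_ie_deg": truth.ie_deg,
        "true_ap_med_mm": truth.ap_med_mm,
        "true_ap_lat_mm": truth.ap_lat_mm,
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ground-truth CSV {path} missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# model directories (meshes + landmark sidecar)

_MESH_FIELDS = {
    "native": ["femur", "tibia", "medial_condyle", "lateral_condyle",
               "medial_plateau_patch", "lateral_plateau_patch"],
    "tka": ["femoral_component", "baseplate", "medial_condyle", "lateral_condyle"],
}


def _plane_dict(plane):
    return None if plane is None else {
        "point": list(map(float, plane.point)), "normal": list(map(float, plane.normal))}


def write_model(model, directory: str | Path) -> None:
    """Write a generated model as binary STL parts plus a ``landmarks.json``
    sidecar (spec fields and the analytic landmark record)."""
    from dataclasses import asdict

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _MESH_FIELDS[model.kind]:
        write_mesh(getattr(model, name), directory / f"{name}.stl")
    lm = model.landmarks
    sidecar = {
        "kind": model.kind,
        "spec": asdict(model.spec),
        "landmarks": {
            "medial_condyle_center": list(map(float, lm.medial_condyle_center)),
            "medial_condyle_radius": float(lm.medial_condyle_radius),
            "lateral_condyle_center": list(map(float, lm.lateral_condyle_center)),
            "lateral_condyle_radius": float(lm.lateral_condyle_radius),
            "condylar_axis": {"point": list(map(float, lm.condylar_axis.point)),
                              "direction": list(map(float, lm.condylar_axis.direction))},
            "medial_plateau_plane": _plane_dict(lm.medial_plateau_plane),
            "lateral_plateau_plane": _plane_dict(lm.lateral_plateau_plane),
            "tibial_medial_center": list(map(float, lm.tibial_medial_center)),
            "tibial_lateral_center": list(map(float, lm.tibial_lateral_center)),
            "joint_line_z": float(lm.joint_line_z),
            "baseplate_center": (None if lm.baseplate_center is None
                                 else list(map(float, lm.baseplate_center))),
            "baseplate_plane": _plane_dict(lm.baseplate_plane),
            "baseplate_ap_depth": (None if lm.baseplate_ap_depth is None
                                   else float(lm.baseplate_ap_depth)),
        },
    }
    (directory / "landmarks.json").write_text(json.dumps(sidecar, indent=1))


def read_model(directory: str | Path):
    """Reload a model directory written by :func:`write_model`."""
    from ._geom import Line, Plane
    from . import synthetic as syn

    directory = Path(directory)
    sidecar_path = directory / "landmarks.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing landmark sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    kind = sidecar["kind"]
    if kind not in _MESH_FIELDS:
        raise FormatError(f"unknown model kind {kind!r} in {sidecar_path}")
    meshes = {name: read_mesh(directory / f"{name}.stl") for name in _MESH_FIELDS[kind]}
    lmd = sidecar["landmarks"]

    def plane(d):
        return None if d is None else Plane(d["point"], d["normal"])

    landmarks = syn.Landmarks(
        medial_condyle_center=np.array(lmd["medial_condyle_center"]),
        medial_condyle_radius=lmd["medial_condyle_radius"],
        lateral_condyle_center=np.array(lmd["lateral_condyle_center"]),
        lateral_condyle_radius=lmd["lateral_condyle_radius"],
        condylar_axis=Line(lmd["condylar_axis"]["point"], lmd["condylar_axis"]["direction"]),
        medial_plateau_plane=plane(lmd["medial_plateau_plane"]),
        lateral_plateau_plane=plane(lmd["lateral_plateau_plane"]),
        tibial_medial_center=np.array(lmd["tibial_medial_center"]),
        tibial_lateral_center=np.array(lmd["tibial_lateral_center"]),
        joint_line_z=lmd["joint_line_z"],
        baseplate_center=(None if lmd["baseplate_center"] is None
                          else np.array(lmd["baseplate_center"])),
        baseplate_plane=plane(lmd["baseplate_plane"]),
        baseplate_ap_depth=lmd["baseplate_ap_depth"],
    )
    if kind == "native":
        return syn.KneeModel(spec=syn.KneeSpec(**sidecar["spec"]),
                             landmarks=landmarks, **meshes)
    return syn.TKAModel(spec=syn.TKASpec(**sidecar["spec"]),
                        landmarks=landmarks, **meshes)


# ---------------------------------------------------------------------------
# config helpers


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, recorded in outputs
    so that identical config + seed is verifiable from the artifacts."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    return cfg
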