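"""Core domain types shared by every pipeline stage.

Conventions
-----------
* Volumes are stored in ``(z, y, x)`` axis order: axis 0 walks axial
  slices along the patient's long axis, axis 1 is the image row
  (anterior at low row index for a supine patient) and axis 2 the
  image column.
* ``spacing`` and ``origin`` are expressed per *world* axis ``(x, y, z)``
  in millimetres, so the world coordinate of voxel ``(k, j, i)`` is
  ``origin + (i * sx, j * sy, k * sz)``.
* Rigid transforms carry a proper rotation (no scale, no reflection)
  and a translation in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ScalarVolume",
    "BinaryVolume",
    "TriangleMesh",
    "PointSet",
    "RigidTransform",
    "apply_transform",
    "compose",
    "voxel_to_world",
    "world_to_voxel",
]

_ORTHO_TOL = 1e-8


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


@dataclass
class ScalarVolume:
    """A 3D intensity grid (HU-like arbitrary units) with geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvariantError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise InvariantError(f"every axis must have size >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise InvariantError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise InvariantError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.spacing, self.origin)


@dataclass
class BinaryVolume:
    """A per-voxel {0,1} label volume (skin mask, lesion mask)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvariantError(f"mask data must be 3D, got ndim={self.data.ndim}")
        uniq = np.unique(self.data)
        if not np.isin(uniq, (0, 1)).all():
            raise InvariantError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InvariantError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "BinaryVolume":
        return BinaryVolume(self.data.copy(), self.spacing, self.origin)


def voxel_to_world(
    index_zyx: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
) -> np.ndarray:
    """Map (k, j, i) voxel indices to world-mm (x, y, z) points."""
    idx = np.atleast_2d(np.asarray(index_zyx, dtype=float))
    sx, sy, sz = spacing
    ox, oy, oz = origin
    out = np.column_stack(
        [ox + idx[:, 2] * sx, oy + idx[:, 1] * sy, oz + idx[:, 0] * sz]
    )
    return out if np.asarray(index_zyx).ndim > 1 else out[0]


def world_to_voxel(
    points_xyz: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns float (k, j, i) indices."""
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    sx, sy, sz = spacing
    ox, oy, oz = origin
    out = np.column_stack(
        [(pts[:, 2] - oz) / sz, (pts[:, 1] - oy) / sy, (pts[:, 0] - ox) / sx]
    )
    return out if np.asarray(points_xyz).ndim > 1 else out[0]


@dataclass
class TriangleMesh:
    """Vertices (n,3) world-mm and faces (m,3) vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise InvariantError("face indices out of vertex range")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise InvariantError("faces with repeated vertices are not allowed")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class PointSet:
    """An unordered set of 3D points in world millimetres."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        if len(self.points) == 0:
            raise InvariantError("centroid of an empty point set is undefined")
        return self.points.mean(axis=0)


@dataclass
class RigidTransform:
    """A proper rigid motion p -> R @ p + t (rotation then translation).

    Scale is deliberately excluded: the virtual (CT) and real (scan)
    surfaces describe the same patient, so only rotation + translation
    are estimated anywhere in the toolkit.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise InvariantError(f"rotation is not orthonormal (max |R^T R - I| = {err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise InvariantError(f"rotation must be proper (det=+1), got det={det:.6f}")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path) -> None:
        payload = {"matrix": self.as_matrix().tolist(), "units": "mm", "order": "row-major"}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        return cls.from_matrix(np.asarray(payload["matrix"]))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Return the transform equivalent to applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def apply_transform(t: RigidTransform, target):
    """Apply a rigid transform to a mesh, point set or bare point array.

    Topology (faces, point order) is untouched; only coordinates move.
    """
    if isinstance(target, TriangleMesh):
        return TriangleMesh(t.apply(target.vertices), target.faces.copy())
    if isinstance(target, PointSet):
        return PointSet(t.apply(target.points))
    return t.apply(np.asarray(target, dtype=float))
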