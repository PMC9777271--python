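"""Readers and writers for volumes, meshes, point clouds and transforms.

Volumes go through SimpleITK (NIfTI ``.nii``/``.nii.gz`` and NRRD
``.nrrd``); meshes and point clouds go through trimesh (PLY, OBJ, STL).
Identity orientation is assumed throughout: volumes whose direction
cosines are not the identity are reoriented to the closest axis-aligned
frame on read, with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .core import BinaryVolume, PointSet, ScalarVolume, TriangleMesh

__all__ = [
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_point_set",
    "write_point_set",
    "FormatError",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".nrrd")
_MESH_FORMATS = ("ply", "obj", "stl")


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as the requested format."""


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(
            f"unsupported volume format for {path.name!r}; expected one of {_VOLUME_SUFFIXES}"
        )


def read_volume(path) -> ScalarVolume:
    """Read a NIfTI or NRRD volume into ``(z, y, x)`` axis order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_volume_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - exercised via bad files
        raise FormatError(f"could not read volume header of {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(
            f"expected a 3D volume, got dimension={img.GetDimension()} in {path.name}"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        warnings.warn(
            f"{path.name}: non-identity direction cosines; reorienting to axis-aligned",
            stacklevel=2,
        )
        img = sitk.DICOMOrient(img, "LPS")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(float(s) for s in img.GetSpacing())  # (sx, sy, sz)
    origin = tuple(float(o) for o in img.GetOrigin())
    if any(s <= 0 for s in spacing):
        raise FormatError(f"invalid spacing {spacing} in header of {path.name}")
    return ScalarVolume(data, spacing, origin)


def write_volume(vol: ScalarVolume | BinaryVolume, path) -> None:
    """Write a volume as NIfTI or NRRD; binary masks are stored as uint8."""
    path = Path(path)
    _check_volume_path(path)
    data = vol.data
    if isinstance(vol, BinaryVolume):
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, str(path))


def read_binary_volume(path) -> BinaryVolume:
    vol = read_volume(path)
    return BinaryVolume((vol.data > 0).astype(np.uint8), vol.spacing, vol.origin)


def _mesh_format(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise FormatError(
            f"unsupported mesh format {fmt!r}; supported formats: {', '.join(_MESH_FORMATS)}"
        )
    return fmt


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a triangle mesh as PLY, OBJ or STL.

    STL stores bare triangle soup, so an empty mesh is representable in
    PLY/OBJ but rejected for STL.
    """
    path = Path(path)
    fmt = _mesh_format(path, fmt)
    if mesh.n_faces == 0 and fmt == "stl":
        raise FormatError("STL cannot represent an empty mesh; use PLY or OBJ")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), file_type=fmt)


def read_mesh(path) -> TriangleMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _mesh_format(path, None)
    tm = trimesh.load(str(path), process=False, force="mesh")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_point_set(ps: PointSet, path) -> None:
    """Write a point cloud as PLY."""
    path = Path(path)
    if path.suffix.lower() != ".ply":
        raise FormatError("point clouds are written as PLY")
    cloud = trimesh.PointCloud(ps.points)
    cloud.export(str(path), file_type="ply")


def read_point_set(path) -> PointSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    loaded = trimesh.load(str(path), process=False)
    return PointSet(np.asarray(loaded.vertices))
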