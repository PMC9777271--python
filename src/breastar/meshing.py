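"""Skin-mesh generation, simplification and ROI vertex selection.

The binary skin mask is cast to a float occupancy field, Gaussian
smoothed (to suppress slice-thickness staircase aliasing without slice
interpolation) and polygonized with marching cubes at the 0.5
isosurface. The resulting mesh is simplified to a face budget with a
fast quadric edge-collapse scheme, and registration vertices are
selected as the metric ball around a nipple-derived centre — the
exposed surgical field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .core import BinaryVolume, PointSet, TriangleMesh
from .nipples import NipplePair
from .preprocess import ScalarVolume, gaussian_smooth

__all__ = [
    "MeshingParams",
    "extract_surface",
    "decimate",
    "select_roi_vertices",
    "quadric_error",
]


class EmptyMaskError(ValueError):
    pass


@dataclass
class MeshingParams:
    """Surface extraction / decimation / ROI parameters.

    target_faces defaults to the full-resolution registration budget of
    192,000 faces; studies on small phantoms use a few thousand.
    roi_center selects which surgical site centres the ROI ball:
    'midpoint' (between the nipples), 'left' or 'right'.
    """

    iso_level: float = 0.5
    smooth_sigma_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    target_faces: int = 192_000
    roi_radius_mm: float = 100.0
    roi_center: str = "midpoint"
    anterior_filter: bool = True
    anterior_axis: tuple[float, float, float] = (0.0, -1.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.iso_level < 1.0):
            raise ValueError("iso_level must lie in (0, 1)")
        if self.target_faces < 4:
            raise ValueError("target_faces must be >= 4")
        if self.roi_radius_mm <= 0:
            raise ValueError("roi_radius_mm must be > 0")
        if self.roi_center not in ("midpoint", "left", "right"):
            raise ValueError("roi_center must be 'midpoint', 'left' or 'right'")


def extract_surface(mask: BinaryVolume, p: MeshingParams | None = None) -> TriangleMesh:
    """Marching-cubes isosurface of the smoothed occupancy field.

    Vertices are returned in world millimetres (spacing and origin
    applied). On a closed mask the output is watertight: every edge is
    shared by exactly two faces.
    """
    p = p or MeshingParams()
    if not mask.data.any():
        raise EmptyMaskError("cannot extract a surface from an empty mask")
    occupancy = ScalarVolume(mask.data.astype(float), mask.spacing, mask.origin)
    if any(s > 0 for s in p.smooth_sigma_mm):
        occupancy = gaussian_smooth(occupancy, p.smooth_sigma_mm)
    field_ = np.pad(occupancy.data, 1, mode="constant")  # guarantee closure at borders
    sx, sy, sz = mask.spacing
    verts, faces, _, _ = measure.marching_cubes(
        field_, level=p.iso_level, spacing=(sz, sy, sx)
    )
    # marching_cubes coordinates are (z, y, x); shift for the pad, map to world
    ox, oy, oz = mask.origin
    world = np.column_stack(
        [verts[:, 2] - sx + ox, verts[:, 1] - sy + oy, verts[:, 0] - sz + oz]
    )
    return TriangleMesh(world, faces)


def quadric_error(Q: np.ndarray, v: np.ndarray) -> float:
    """Evaluate the quadric form v^T Q v at homogeneous point v=(x,y,z,1)."""
    h = np.append(np.asarray(v, dtype=float), 1.0)
    return float(h @ Q @ h)


def _face_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-face fundamental error quadrics K = p p^T, p = (n, d), |n| = 1."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(v1 - v0, v2 - v0)
    area = np.linalg.norm(n, axis=1)
    good = area > 1e-300
    n[good] /= area[good][:, None]
    d = -(n * v0).sum(axis=1)
    p = np.concatenate([n, d[:, None]], axis=1)  # (m, 4)
    return p[:, :, None] * p[:, None, :]  # (m, 4, 4)


def _vertex_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    K = _face_quadrics(vertices, faces)
    Q = np.zeros((len(vertices), 4, 4))
    for i in range(3):
        np.add.at(Q, faces[:, i], K)
    return Q


def _optimal_positions(
    Q: np.ndarray, fallback: np.ndarray, edge_scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge optimal collapse target; midpoint fallback for singular quadrics."""
    A = Q[:, :3, :3]
    b = -Q[:, :3, 3]
    pos = fallback.copy()
    # solve the well-conditioned systems in one batch
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-9 * (np.abs(A).max(axis=(1, 2)) ** 3 + 1e-300)
    if ok.any():
        pos[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
    # reject solutions that fly far from the edge (ill-conditioned quadrics)
    far = np.linalg.norm(pos - fallback, axis=1) > 10.0 * edge_scale
    pos[far] = fallback[far]
    h = np.concatenate([pos, np.ones((len(pos), 1))], axis=1)
    err = np.einsum("ij,ijk,ik->i", h, Q, h)
    return pos, np.maximum(err, 0.0)


def _unique_edges(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def decimate(mesh: TriangleMesh, target_faces: int) -> TriangleMesh:
    """Fast quadric edge-collapse simplification to a face budget.

    Batched greedy variant of the Garland–Heckbert scheme: each pass
    evaluates the collapse cost of every edge from accumulated vertex
    quadrics, sorts ascending, and greedily collapses non-interacting
    edges (no shared endpoint within a pass) into their optimal-quadric
    position until the face budget is met. Deterministic: no randomness,
    ties broken by edge index. A mesh already at or under budget is
    returned unchanged.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    if mesh.n_faces <= target_faces:
        return mesh
    vertices = mesh.vertices.copy()
    faces = mesh.faces.copy()
    while len(faces) > target_faces:
        edges = _unique_edges(faces)
        seg = vertices[edges[:, 1]] - vertices[edges[:, 0]]
        edge_scale = float(np.linalg.norm(seg, axis=1).mean()) or 1.0
        Qv = _vertex_quadrics(vertices, faces)
        Qe = Qv[edges[:, 0]] + Qv[edges[:, 1]]
        midpoints = 0.5 * (vertices[edges[:, 0]] + vertices[edges[:, 1]])
        pos, err = _optimal_positions(Qe, midpoints, edge_scale)
        order = np.argsort(err, kind="stable")
        n_needed = (len(faces) - target_faces + 1) // 2  # each collapse kills ~2 faces
        touched = np.zeros(len(vertices), dtype=bool)
        mapping = np.arange(len(vertices))
        n_done = 0
        for ei in order:
            a, b = edges[ei]
            if touched[a] or touched[b]:
                continue
            vertices[a] = pos[ei]
            mapping[b] = a
            touched[a] = touched[b] = True
            n_done += 1
            if n_done >= n_needed:
                break
        if n_done == 0:
            break  # no further non-conflicting collapse possible
        faces = mapping[faces]
        degenerate = (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
        faces = faces[~degenerate]
        # drop duplicated faces that can appear when fans collapse together
        key = np.sort(faces, axis=1)
        _, idx = np.unique(key, axis=0, return_index=True)
        faces = faces[np.sort(idx)]
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices[used], remap[faces])


def roi_center_point(nipples: NipplePair, roi_center: str) -> np.ndarray:
    if roi_center == "left":
        return nipples.left
    if roi_center == "right":
        return nipples.right
    return 0.5 * (nipples.left + nipples.right)


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted outward vertex normals of a closed mesh.

    Face orientation is taken as globally consistent (marching cubes
    guarantees it); the global sign is fixed so that normals point away
    from the surface centroid on average.
    """
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # area-weighted
    n = np.zeros_like(v)
    for i in range(3):
        np.add.at(n, f[:, i], fn)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norms, out=np.zeros_like(n), where=norms > 0)
    outwardness = float(np.mean(np.sum(n * (v - v.mean(axis=0)), axis=1)))
    return -n if outwardness < 0 else n


def select_roi_vertices(
    mesh: TriangleMesh, nipples: NipplePair, p: MeshingParams | None = None
) -> PointSet:
    """Vertices within the ROI ball around the configured nipple centre.

    The ball selection is exactly {v : |v - c| <= r}. With
    ``anterior_filter`` enabled (the default), vertices whose outward
    normal has no component along the anterior axis are dropped as
    well — the depth sensor only ever sees the exposed anterior field,
    so posterior and far-lateral skin would have no counterpart in the
    scan and only mislead the registration.

    An empty result raises with the radius and the distance to the
    nearest vertex, so the user can see how far off the configuration is.
    """
    p = p or MeshingParams()
    center = roi_center_point(nipples, p.roi_center)
    keep = np.ones(mesh.n_vertices, dtype=bool)
    if p.anterior_filter:
        anterior = np.asarray(p.anterior_axis, dtype=float)
        anterior = anterior / np.linalg.norm(anterior)
        keep &= vertex_normals(mesh) @ anterior > 0
    if np.isfinite(p.roi_radius_mm):
        keep &= np.linalg.norm(mesh.vertices - center, axis=1) <= p.roi_radius_mm
    if not keep.any():
        nearest, _ = cKDTree(mesh.vertices).query(center)
        raise ValueError(
            f"no vertex within roi_radius_mm={p.roi_radius_mm} "
            f"(anterior_filter={p.anterior_filter}); nearest vertex is "
            f"{nearest:.2f} mm from the ROI centre"
        )
    return PointSet(mesh.vertices[keep])
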