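"""Rigid alignment of the CT-derived ROI vertices to the patient scan.

Two stages, mirroring how a surface scan is brought onto preoperative
CT in image-guided surgery: a centre-of-mass translation for coarse
alignment, then point-to-point ICP. Each ICP iteration finds
nearest-neighbour correspondences with a KD-tree, optionally rejects
distant pairs and trims the worst fraction (the scan covers only part
of the exposed field), and solves the closed-form least-squares rigid
fit (SVD of the cross-covariance, reflection corrected). No scale is
ever estimated: both surfaces belong to the same patient.

The reported FRE (fiducial registration error) is the RMS of
corresponding-point distances at convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import PointSet, RigidTransform, TriangleMesh, compose

__all__ = [
    "ICPParams",
    "RegistrationResult",
    "center_of_mass_align",
    "best_fit_rigid",
    "icp",
    "register",
    "fiducial_registration_error",
]


class DegenerateGeometryError(RuntimeError):
    """Correspondences do not constrain a rigid transform."""


@dataclass
class ICPParams:
    max_iterations: int = 100
    convergence_tol: float = 1e-4  # mm change in RMS between iterations
    max_correspondence_dist: float = np.inf  # mm
    trim_fraction: float = 0.1  # worst fraction of pairs dropped

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")
        if not (0.0 <= self.trim_fraction < 1.0):
            raise ValueError("trim_fraction must lie in [0, 1)")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    fre_mm: float
    rms_history: list[float] = field(default_factory=list)
    iterations_used: int = 0
    converged: bool = False


def center_of_mass_align(source: PointSet, target: PointSet) -> RigidTransform:
    """Translation that moves the source centroid onto the target centroid."""
    return RigidTransform(np.eye(3), target.centroid() - source.centroid())


def best_fit_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit of paired points (Kabsch/Umeyama).

    Minimizes sum |R s_i + t - t_i|^2 via SVD of the centered
    cross-covariance; a reflection in the SVD solution is corrected by
    flipping the smallest singular direction, keeping det(R) = +1.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("source and target must be matched (n, 3) arrays")
    sc, tc = s.mean(axis=0), t.mean(axis=0)
    H = (s - sc).T @ (t - tc)
    if np.linalg.matrix_rank(H, tol=1e-9 * max(1.0, np.abs(H).max())) < 2:
        raise DegenerateGeometryError(
            "correspondence cross-covariance has rank < 2; geometry does not "
            "constrain the rotation"
        )
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


def _target_points(target) -> np.ndarray:
    if isinstance(target, TriangleMesh):
        return target.vertices
    if isinstance(target, PointSet):
        return target.points
    return np.asarray(target, dtype=float).reshape(-1, 3)


def icp(
    source: PointSet,
    target,
    p: ICPParams | None = None,
    init: RigidTransform | None = None,
) -> RegistrationResult:
    """Point-to-point ICP from ``init``; returns init composed in.

    ``rms_history`` records the (trimmed) RMS at each correspondence
    stage; with a fixed trim fraction this sequence is non-increasing,
    and the last entry is the reported FRE.
    """
    p = p or ICPParams()
    t = init or RigidTransform.identity()
    src = source.points
    if len(src) < 3:
        raise DegenerateGeometryError("ICP needs at least 3 source points")
    tgt = _target_points(target)
    if len(tgt) == 0:
        raise ValueError("empty target")
    tree = cKDTree(tgt)
    rms_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, p.max_iterations + 1):
        moved = t.apply(src)
        dist, idx = tree.query(moved)
        keep = dist <= p.max_correspondence_dist
        if p.trim_fraction > 0 and keep.sum() > 3:
            kept_d = dist[keep]
            cutoff = np.quantile(kept_d, 1.0 - p.trim_fraction)
            keep &= dist <= cutoff
        if keep.sum() < 3:
            raise DegenerateGeometryError(
                "fewer than 3 correspondences survive rejection/trimming"
            )
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        rms_history.append(rms)
        if len(rms_history) > 1 and abs(rms_history[-2] - rms) < p.convergence_tol:
            converged = True
            break
        step = best_fit_rigid(moved[keep], tgt[idx[keep]])
        t = compose(step, t)
    return RegistrationResult(
        transform=t,
        fre_mm=rms_history[-1],
        rms_history=rms_history,
        iterations_used=it,
        converged=converged,
    )


def register(roi: PointSet, scan, p: ICPParams | None = None) -> RegistrationResult:
    """Centre-of-mass pre-alignment followed by ICP refinement.

    The ROI vertices (virtual/CT frame) are the moving source and the
    scan surface (real frame) the fixed target, so the returned
    transform carries CT-space data — for example a segmented lesion
    mesh — into the real coordinate system.
    """
    pre = center_of_mass_align(
        roi, PointSet(_target_points(scan))
    )
    return icp(roi, scan, p, init=pre)


def fiducial_registration_error(source: PointSet, target, t: RigidTransform) -> float:
    """RMS nearest-correspondence distance after applying ``t`` to source."""
    src = source.points
    if len(src) == 0:
        raise ValueError("empty source")
    tgt = _target_points(target)
    if len(tgt) == 0:
        raise ValueError("empty target")
    dist, _ = cKDTree(tgt).query(t.apply(src))
    return float(np.sqrt(np.mean(dist**2)))
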