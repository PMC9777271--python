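"""Synthetic torso phantoms: CT-like volumes with ground truth, and
simulated partial-coverage surface scans under a known rigid transform.

The phantom is a supine chest section built as an anterior height
field: an elliptical-cross-section torso (flat posterior), two
Gaussian-profile breast protrusions topped by a sharper nipple apex,
ellipsoidal lesions embedded in the parenchyma, an optional bright
scanner-pad crescent touching the posterior image border, and additive
Gaussian noise. Because the anterior surface is a single-valued height
field, the generator knows the exact skin surface, nipple apices and
lesion geometry, which it emits as ground truth before noise is added.

``simulate_scan`` samples the same analytic surface inside a coverage
cone around the anterior direction (a hand-held depth sensor sees the
exposed anterior field only), perturbs the points with isotropic
Gaussian noise and moves them by the spec's true rigid transform — the
quantity registration must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BinaryVolume, PointSet, RigidTransform, ScalarVolume
from .nipples import NipplePair

__all__ = ["PhantomSpec", "PhantomTruth", "generate_ct", "simulate_scan"]


@dataclass
class ScanSpec:
    coverage_deg: float = 120.0  # full cone angle about the anterior axis
    n_points: int = 2000
    noise_sigma_mm: float = 1.0
    rotation_axis: tuple[float, float, float] = (0.25, 0.6, 0.76)
    rotation_deg: float = 15.0
    translation_mm: tuple[float, float, float] = (18.0, -20.0, 14.0)


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of the synthetic torso.

    All lengths are millimetres; intensities are HU-like arbitrary
    units. The default volume is an 80-slice chest section at 1 mm
    isotropic spacing, sized so a full pipeline run stays cheap while
    breasts, lesions and pad are all well resolved.
    """

    shape: tuple[int, int, int] = (80, 128, 160)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (sx, sy, sz)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # torso cross-section: anterior surface of a half-ellipse, flat posterior
    torso_center_x: float = 80.0
    torso_halfwidth: float = 70.0  # mm, x semi-axis
    torso_depth: float = 55.0  # mm, anterior extent above the posterior plane
    posterior_y: float = 118.0  # mm, flat posterior plane (large row = posterior)
    z_sag: float = 6.0  # mm recession of the chest wall toward the stack ends
    # breast protrusions (Gaussian bumps + sharper nipple apex)
    bump_centers_xz: tuple[tuple[float, float], ...] = ((48.0, 40.0), (112.0, 40.0))
    bump_amplitude: float = 22.0
    bump_sigma_x: float = 16.0
    bump_sigma_z: float = 14.0
    nipple_amplitude: float = 3.0
    nipple_radius: float = 4.0
    # embedded lesions (ellipsoids): center (x, y, z) and radii (rx, ry, rz)
    lesion_centers: tuple[tuple[float, float, float], ...] = (
        (48.0, 80.0, 40.0),
        (112.0, 78.0, 42.0),
    )
    lesion_radii: tuple[tuple[float, float, float], ...] = (
        (10.0, 9.0, 8.0),
        (8.0, 8.0, 9.0),
    )
    # intensities
    body_intensity: float = 100.0
    lesion_intensity: float = 160.0
    background_intensity: float = 0.0
    noise_sigma: float = 8.0
    # scanner-pad artifact
    pad: bool = True
    pad_intensity: float = 120.0
    pad_thickness: float = 4.0
    scan: ScanSpec = field(default_factory=ScanSpec)
    seed: int = 0


@dataclass
class PhantomTruth:
    skin_mask: BinaryVolume
    nipples: NipplePair
    lesion_mask: BinaryVolume
    scan_transform: RigidTransform


def _surface_height(spec: PhantomSpec, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Anterior surface row coordinate y(x, z) in mm; NaN outside the torso."""
    xr = (x - spec.torso_center_x) / spec.torso_halfwidth
    inside = np.abs(xr) < 1.0
    y = np.full(np.broadcast(x, z).shape, np.nan)
    base = np.sqrt(np.clip(1.0 - xr**2, 0.0, None))
    zc = (np.asarray(z, dtype=float) - _z_center(spec)) / max(_z_half(spec), 1e-9)
    wall = spec.posterior_y - spec.torso_depth * base + spec.z_sag * zc**2
    bump = np.zeros_like(wall)
    for bx, bz in spec.bump_centers_xz:
        g = np.exp(
            -((x - bx) ** 2) / (2 * spec.bump_sigma_x**2)
            - ((z - bz) ** 2) / (2 * spec.bump_sigma_z**2)
        )
        bump = bump + spec.bump_amplitude * g
        r = np.sqrt((x - bx) ** 2 + (z - bz) ** 2)
        apex = np.where(
            r < spec.nipple_radius,
            spec.nipple_amplitude * 0.5 * (1 + np.cos(np.pi * r / spec.nipple_radius)),
            0.0,
        )
        bump = bump + apex
    y = np.where(inside, wall - bump, np.nan)
    return y


def _z_center(spec: PhantomSpec) -> float:
    return 0.5 * (spec.shape[0] - 1) * spec.spacing[2]


def _z_half(spec: PhantomSpec) -> float:
    return 0.5 * (spec.shape[0] - 1) * spec.spacing[2]


def _grids_mm(spec: PhantomSpec):
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    z = np.arange(nz) * sz
    y = np.arange(ny) * sy
    x = np.arange(nx) * sx
    return z, y, x


def nipple_truth(spec: PhantomSpec) -> NipplePair:
    """Analytic apex positions, in world mm."""
    pts = []
    for bx, bz in spec.bump_centers_xz:
        y = float(_surface_height(spec, np.array(bx), np.array(bz)))
        pts.append(
            np.array(
                [bx + spec.origin[0], y + spec.origin[1], bz + spec.origin[2]]
            )
        )
    pts.sort(key=lambda p: p[0])
    return NipplePair(left=pts[0], right=pts[1])


def generate_ct(spec: PhantomSpec | None = None) -> tuple[ScalarVolume, PhantomTruth]:
    """Build the phantom volume and its ground truth.

    Truth (skin mask, nipple positions, lesion mask, scan transform) is
    derived from the clean analytic model before noise is added.
    """
    spec = spec or PhantomSpec()
    nz, ny, nx = spec.shape
    z, y, x = _grids_mm(spec)
    X = x[None, None, :]
    Y = y[None, :, None]
    Z = z[:, None, None]
    ysurf = _surface_height(spec, np.broadcast_to(X, (nz, 1, nx)), np.broadcast_to(Z, (nz, 1, nx)))
    body = (Y >= ysurf) & (Y <= spec.posterior_y)
    body = np.where(np.isnan(ysurf), False, body)
    for (cx, cy, cz), (rx, ry, rz) in zip(spec.lesion_centers, spec.lesion_radii):
        if not bool(
            body[
                min(int(round(cz / spec.spacing[2])), nz - 1),
                min(int(round(cy / spec.spacing[1])), ny - 1),
                min(int(round(cx / spec.spacing[0])), nx - 1),
            ]
        ):
            raise ValueError(f"lesion centre {(cx, cy, cz)} lies outside the torso")
    lesion = np.zeros(spec.shape, dtype=bool)
    for (cx, cy, cz), (rx, ry, rz) in zip(spec.lesion_centers, spec.lesion_radii):
        lesion |= (
            ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2
        ) <= 1.0
    lesion &= body
    vol = np.full(spec.shape, spec.background_intensity, dtype=float)
    vol[body] = spec.body_intensity
    vol[lesion] = spec.lesion_intensity
    if spec.pad:
        pad_mask = _pad_mask(spec, X, Y, Z, body)
        vol[pad_mask] = spec.pad_intensity
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    geometry = (spec.spacing, spec.origin)
    truth = PhantomTruth(
        skin_mask=BinaryVolume(body.astype(np.uint8), *geometry),
        nipples=nipple_truth(spec),
        lesion_mask=BinaryVolume(lesion.astype(np.uint8), *geometry),
        scan_transform=RigidTransform.from_axis_angle(
            spec.scan.rotation_axis, spec.scan.rotation_deg, spec.scan.translation_mm
        ),
    )
    return ScalarVolume(vol, *geometry), truth


def _pad_mask(spec: PhantomSpec, X, Y, Z, body: np.ndarray) -> np.ndarray:
    """A shallow crescent posterior to the body, touching the posterior
    image border, separated from the body by a clear background gap so it
    is a distinct connected component (as a real scanner pad is)."""
    xr = (X - spec.torso_center_x) / spec.torso_halfwidth
    y_top = spec.posterior_y + 5.0 + 8.0 * xr**2  # sags away from the body
    crescent = (
        (Y >= y_top)
        & (Y <= y_top + spec.pad_thickness)
        & (np.abs(xr) < 0.8)
    )
    crescent = np.broadcast_to(crescent, body.shape).copy()
    crescent &= ~body
    return crescent


def simulate_scan(
    spec: PhantomSpec, truth: PhantomTruth | None = None, rng: np.random.Generator | None = None
) -> tuple[PointSet, RigidTransform]:
    """Sample a partial noisy surface scan of the phantom.

    Points are drawn on the analytic anterior surface where the outward
    normal lies within half the coverage angle of the anterior axis,
    jittered with isotropic Gaussian noise, then mapped through the
    spec's true rigid transform (returned as ground truth).
    """
    if spec.scan.coverage_deg <= 0:
        raise ValueError("scan coverage must be > 0 degrees")
    rng = rng or np.random.default_rng(spec.seed + 1)
    t_true = (
        truth.scan_transform
        if truth is not None
        else RigidTransform.from_axis_angle(
            spec.scan.rotation_axis, spec.scan.rotation_deg, spec.scan.translation_mm
        )
    )
    n_target = spec.scan.n_points
    cos_half = np.cos(np.deg2rad(spec.scan.coverage_deg / 2.0))
    zmax = (spec.shape[0] - 1) * spec.spacing[2]
    pts = []
    eps = 1e-3
    n_drawn = 0
    while sum(len(p) for p in pts) < n_target and n_drawn < 60 * n_target:
        m = 4 * n_target
        n_drawn += m
        xs = spec.torso_center_x + (rng.random(m) * 2 - 1) * spec.torso_halfwidth * 0.98
        zs = rng.random(m) * zmax
        ys = _surface_height(spec, xs, zs)
        ok = ~np.isnan(ys)
        xs, zs, ys = xs[ok], zs[ok], ys[ok]
        # outward (anterior) normal of the height field y = f(x, z): (-fx, -1, -fz)
        fx = (_surface_height(spec, xs + eps, zs) - _surface_height(spec, xs - eps, zs)) / (2 * eps)
        fz = (_surface_height(spec, xs, zs + eps) - _surface_height(spec, xs, zs - eps)) / (2 * eps)
        cos_a = 1.0 / np.sqrt(1.0 + fx**2 + fz**2)  # angle to the anterior axis
        keep = np.isfinite(cos_a) & (cos_a >= cos_half)
        pts.append(np.column_stack([xs[keep], ys[keep], zs[keep]]))
    points = np.concatenate(pts)[:n_target]
    if len(points) == 0:
        raise ValueError("scan coverage selected no surface points")
    points = points + np.asarray(spec.origin)[None, :]
    if spec.scan.noise_sigma_mm > 0:
        points = points + rng.normal(0.0, spec.scan.noise_sigma_mm, size=points.shape)
    return PointSet(t_true.apply(points)), t_true


def randomized_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """A per-case variation of ``base``: jittered breast/lesion geometry and
    a scan transform with fixed 15 degree / 30 mm magnitude but random
    direction — different patients scanned from different angles."""
    bumps = tuple(
        (bx + rng.uniform(-6, 6), bz + rng.uniform(-5, 5))
        for bx, bz in base.bump_centers_xz
    )
    amp = base.bump_amplitude + rng.uniform(-4, 4)
    lesions = tuple(
        (cx + rng.uniform(-4, 4), cy + rng.uniform(-4, 4), cz + rng.uniform(-3, 3))
        for cx, cy, cz in base.lesion_centers
    )
    radii = tuple(
        tuple(float(np.clip(r + rng.uniform(-2, 2), 6.0, 12.0)) for r in rr)
        for rr in base.lesion_radii
    )
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    tdir = rng.normal(size=3)
    tdir = tdir / np.linalg.norm(tdir) * 30.0
    scan = replace(
        base.scan,
        rotation_axis=tuple(axis),
        rotation_deg=base.scan.rotation_deg,
        translation_mm=tuple(tdir),
    )
    return replace(
        base,
        bump_centers_xz=bumps,
        bump_amplitude=float(amp),
        lesion_centers=lesions,
        lesion_radii=radii,
        scan=scan,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
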