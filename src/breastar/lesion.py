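"""2.5D lesion segmentation by slice-wise region growing with seed propagation.

A user supplies one seed voxel inside the lesion. The seed slice is
segmented in 2D with seeded region growing followed by morphological
clean-up and hole filling. The result is then propagated to the
adjacent slices: the distance transform of the current slice's mask is
thresholded to keep only its conservative core, which seeds the region
growing on the next slice. Propagation runs independently in +z and
-z and stops when a slice yields nothing or the stack boundary is
reached, so the output is always a contiguous slab of slices around
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryVolume, ScalarVolume
from .skin import SRGParams, seeded_region_grow

__all__ = [
    "LesionConfig",
    "segment_lesion_slice",
    "shrink_seed",
    "segment_lesion_volume",
]


@dataclass
class LesionConfig:
    """Lesion-growing parameters.

    tolerance
        Absolute intensity tolerance for region growing. When None it
        is estimated per seed slice as ``tolerance_factor`` times the
        robust (MAD-based) noise level of the slice.
    erosion_mm
        Distance-map threshold applied before propagating a slice
        result to its neighbour; only the core at least this deep
        inside the region survives as the next seed.
    """

    tolerance: float | None = None
    tolerance_factor: float = 3.0
    erosion_mm: float = 2.0
    opening_size: int = 3
    opening_iterations: int = 1


def _mad_sigma(img: np.ndarray) -> float:
    """Robust per-pixel noise scale of a structured slice.

    MAD of the residual against a 3x3 median filter, scaled to be
    consistent with a Gaussian sigma; the median filter removes anatomy
    so only pixel noise contributes.
    """
    img = np.asarray(img, dtype=float)
    resid = img - ndimage.median_filter(img, size=3)
    return 1.4826 * float(np.median(np.abs(resid)))


def segment_lesion_slice(
    slice_: np.ndarray, seed_region: np.ndarray, tol: float, opening_size: int = 3,
    opening_iterations: int = 1, criterion: float | None = None,
) -> np.ndarray:
    """Region-grow from every seed pixel, then open and fill holes.

    ``criterion`` fixes the region reference intensity (the lesion mean
    estimated on the seed slice); left at None, the mean under the seed
    region of *this* slice is used. An empty grown region returns an
    all-zero mask — the propagation terminator, not an error.
    """
    seed_region = np.asarray(seed_region) > 0
    if not seed_region.any():
        return np.zeros(np.asarray(slice_).shape, dtype=np.uint8)
    seeds = [tuple(rc) for rc in np.argwhere(seed_region)]
    grown = seeded_region_grow(
        slice_, SRGParams(seeds=seeds, similarity_tol=tol, criterion=criterion)
    )
    if not grown.any():
        return np.zeros_like(grown)
    selem = np.ones((opening_size, opening_size), dtype=bool)
    mask = grown.astype(bool)
    if opening_iterations:
        mask = ndimage.binary_opening(mask, structure=selem, iterations=opening_iterations)
    mask = ndimage.binary_fill_holes(mask)
    # keep only components that belong to the seeded growth (opening may
    # have eroded the seed pixels themselves, so test against the whole
    # grown region rather than the bare seeds)
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    seed_labels = np.unique(labels[(grown > 0) & (labels > 0)])
    if len(seed_labels) == 0:
        return np.zeros_like(grown)
    return np.isin(labels, seed_labels).astype(np.uint8)


def shrink_seed(mask: np.ndarray, erosion_mm: float, pixel_mm: float = 1.0) -> np.ndarray:
    """Distance-map core of a mask: pixels strictly deeper than ``erosion_mm``.

    The strict comparison reproduces morphological erosion by a disc of
    that radius (a radius-10 disc eroded by 4 leaves a radius-6 core).
    """
    if erosion_mm < 0:
        raise ValueError("erosion_mm must be >= 0")
    m = np.asarray(mask) > 0
    if erosion_mm == 0 or not m.any():
        return m.astype(np.uint8)
    dist = ndimage.distance_transform_edt(m, sampling=pixel_mm)
    return (dist > erosion_mm).astype(np.uint8)


def segment_lesion_volume(
    vol: ScalarVolume, seed: tuple[int, int, int], cfg: LesionConfig | None = None
) -> BinaryVolume:
    """Segment a lesion from one seed voxel ``(k, j, i)`` by 2.5D propagation."""
    cfg = cfg or LesionConfig()
    k0, j0, i0 = (int(v) for v in seed)
    nz, ny, nx = vol.shape
    if not (0 <= k0 < nz and 0 <= j0 < ny and 0 <= i0 < nx):
        raise ValueError(f"seed {seed} outside volume of shape {vol.shape}")
    tol = cfg.tolerance
    if tol is None:
        tol = cfg.tolerance_factor * max(_mad_sigma(vol.data[k0]), 1e-6)
    seed_mask = np.zeros((ny, nx), dtype=np.uint8)
    seed_mask[j0, i0] = 1
    out = np.zeros(vol.shape, dtype=np.uint8)
    first = segment_lesion_slice(
        vol.data[k0], seed_mask, tol, cfg.opening_size, cfg.opening_iterations
    )
    if not first.any():
        return BinaryVolume(out, vol.spacing, vol.origin)
    # re-centre the region criterion on the mean of the first-pass region
    # (a single seed pixel is a noisy reference) and freeze it, so the
    # reference cannot drift into surrounding tissue during propagation
    criterion = float(vol.data[k0][first > 0].mean())
    first = segment_lesion_slice(
        vol.data[k0], first, tol, cfg.opening_size, cfg.opening_iterations,
        criterion=criterion,
    )
    out[k0] = first
    if not first.any():
        return BinaryVolume(out, vol.spacing, vol.origin)
    criterion = float(vol.data[k0][first > 0].mean())
    pixel_mm = min(vol.spacing[0], vol.spacing[1])
    for direction in (+1, -1):
        prev = first
        k = k0 + direction
        while 0 <= k < nz:
            seed_region = shrink_seed(prev, cfg.erosion_mm, pixel_mm)
            if not seed_region.any():
                break
            cur = segment_lesion_slice(
                vol.data[k], seed_region, tol, cfg.opening_size,
                cfg.opening_iterations, criterion=criterion,
            )
            if not cur.any():
                break
            out[k] = cur
            prev = cur
            k += direction
    return BinaryVolume(out, vol.spacing, vol.origin)
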