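"""Contrast-based skin (body-region) segmentation of axial CT slices.

Per slice: Otsu's data-adaptive threshold binarizes patient vs
background; seeded region growing (SRG) from a point near the image
centre keeps the body and drops disconnected bright structures such as
scanner pads; SRG from a background seed at the image border finds the
exterior, so any background not reachable from outside is an interior
hole and is filled; a final morphological opening removes noise specks
while preserving the skin outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryVolume, ScalarVolume

__all__ = [
    "OtsuStatistics",
    "SRGParams",
    "SkinConfig",
    "otsu_threshold",
    "binarize",
    "seeded_region_grow",
    "segment_skin_slice",
    "segment_skin_volume",
]

_EIGHT = np.ones((3, 3), dtype=bool)


class DegenerateInputError(ValueError):
    """The input has no contrast to threshold."""


@dataclass
class OtsuStatistics:
    """Threshold and the class statistics behind it.

    ``sigma_between`` is the between-class variance at the chosen
    threshold; it equals ``omega0 * omega1 * (mu1 - mu0)**2``.
    """

    threshold: float
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    muT: float
    sigma_between: float


@dataclass
class SRGParams:
    """Seeded-region-growing parameters.

    seeds
        (row, col) pixel coordinates; the region criterion is the mean
        intensity over the seed pixels.
    similarity_tol
        Maximum absolute difference from the criterion for a pixel to
        join the region. 0 demands an exact match (the natural setting
        on binary masks).
    criterion
        Fixed region reference intensity; when None (default) the mean
        of the seed pixel values is used.
    """

    seeds: list[tuple[int, int]] = field(default_factory=list)
    similarity_tol: float = 0.0
    criterion: float | None = None

    def __post_init__(self) -> None:
        if not len(self.seeds):
            raise ValueError("SRG requires at least one seed point")
        if self.similarity_tol < 0:
            raise ValueError("similarity_tol must be >= 0")


@dataclass
class SkinConfig:
    """Knobs of the per-slice skin recipe."""

    n_bins: int = 256
    opening_size: int = 3
    opening_iterations: int = 1
    closing_iterations: int = 0


def otsu_threshold(slice_: np.ndarray, n_bins: int = 256) -> OtsuStatistics:
    """Otsu's threshold over an ``n_bins``-bin histogram of the slice.

    The returned threshold maximizes the between-class variance; ties
    break toward the smallest threshold. Binarization convention is
    strict: a pixel belongs to the foreground iff value > threshold.
    """
    img = np.asarray(slice_, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise DegenerateInputError("constant slice: Otsu threshold is undefined")
    hist, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    w0 = np.cumsum(p)
    m_cum = np.cumsum(p * centers)
    muT = m_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m_cum / w0
        mu1 = (muT - m_cum) / w1
        sigma_b = w0 * w1 * (mu1 - mu0) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    # argmax returns the first (smallest) maximizer: the tie-break rule
    k = int(np.argmax(sigma_b))
    return OtsuStatistics(
        threshold=float(centers[k]),
        omega0=float(w0[k]),
        omega1=float(w1[k]),
        mu0=float(mu0[k]),
        mu1=float(mu1[k]),
        muT=float(muT),
        sigma_between=float(sigma_b[k]),
    )


def binarize(slice_: np.ndarray, stats: OtsuStatistics) -> np.ndarray:
    """Patient region -> 1 (bright on CT), background -> 0."""
    return (np.asarray(slice_, dtype=float) > stats.threshold).astype(np.uint8)


def seeded_region_grow(image: np.ndarray, p: SRGParams) -> np.ndarray:
    """Grow 8-connected regions from seed pixels by intensity similarity.

    The criterion is the mean of the seed values; the grown region is
    the union of 8-connected components of ``|I - criterion| <= tol``
    that contain a seed. Growth continues until no similar pixel is
    adjacent, which this connected-component formulation reaches in one
    labelling pass.
    """
    img = np.asarray(image, dtype=float)
    rows = np.array([s[0] for s in p.seeds])
    cols = np.array([s[1] for s in p.seeds])
    if (
        (rows < 0).any()
        or (cols < 0).any()
        or (rows >= img.shape[0]).any()
        or (cols >= img.shape[1]).any()
    ):
        bad = [
            s
            for s in p.seeds
            if not (0 <= s[0] < img.shape[0] and 0 <= s[1] < img.shape[1])
        ]
        raise ValueError(f"seed(s) out of image bounds: {bad}")
    criterion = p.criterion if p.criterion is not None else img[rows, cols].mean()
    candidate = np.abs(img - criterion) <= p.similarity_tol
    labels, _ = ndimage.label(candidate, structure=_EIGHT)
    seed_labels = np.unique(labels[rows, cols])
    seed_labels = seed_labels[seed_labels > 0]
    return np.isin(labels, seed_labels).astype(np.uint8)


def _nearest_foreground_to_center(binary: np.ndarray) -> tuple[int, int]:
    fg = np.argwhere(binary > 0)
    center = (np.asarray(binary.shape, dtype=float) - 1) / 2.0
    d2 = ((fg - center) ** 2).sum(axis=1)
    r, c = fg[int(np.argmin(d2))]
    return int(r), int(c)


def _background_seed(binary: np.ndarray) -> tuple[int, int] | None:
    """Background seed at top-centre, falling back to bottom-centre."""
    mid = binary.shape[1] // 2
    for r in (0, binary.shape[0] - 1):
        if binary[r, mid] == 0:
            return (r, mid)
    # fall back to any border background pixel
    border = np.zeros_like(binary, dtype=bool)
    border[0] = border[-1] = True
    border[:, 0] = border[:, -1] = True
    cand = np.argwhere(border & (binary == 0))
    if len(cand):
        return (int(cand[0][0]), int(cand[0][1]))
    return None


def segment_skin_slice(slice_: np.ndarray, cfg: SkinConfig | None = None) -> np.ndarray:
    """Full per-slice skin recipe; returns a {0,1} mask.

    A slice without any bright content (stacks can start or end
    off-body) yields an all-zero mask with a warning, not an error.
    """
    cfg = cfg or SkinConfig()
    img = np.asarray(slice_, dtype=float)
    try:
        stats = otsu_threshold(img, cfg.n_bins)
    except DegenerateInputError:
        warnings.warn("constant slice; returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint8)
    binary = binarize(img, stats)
    if not binary.any():
        warnings.warn("no foreground pixel after thresholding; empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint8)
    # body: component containing the foreground pixel nearest the centre
    body_seed = _nearest_foreground_to_center(binary)
    body = seeded_region_grow(binary, SRGParams(seeds=[body_seed], similarity_tol=0.0))
    # exterior background from a border seed; unreachable background = holes
    bg_seed = _background_seed(binary)
    if bg_seed is not None:
        exterior = seeded_region_grow(
            binary, SRGParams(seeds=[bg_seed], similarity_tol=0.0)
        )
        holes = (binary == 0) & (exterior == 0)
    else:  # foreground touches the whole border; nothing to fill from
        holes = np.zeros_like(binary, dtype=bool)
    mask = ((body > 0) | holes).astype(np.uint8)
    selem = np.ones((cfg.opening_size, cfg.opening_size), dtype=bool)
    if cfg.opening_iterations:
        mask = ndimage.binary_opening(
            mask, structure=selem, iterations=cfg.opening_iterations
        )
    if cfg.closing_iterations:
        mask = ndimage.binary_closing(
            mask, structure=selem, iterations=cfg.closing_iterations
        )
    return mask.astype(np.uint8)


def segment_skin_volume(vol: ScalarVolume, cfg: SkinConfig | None = None) -> BinaryVolume:
    """Apply :func:`segment_skin_slice` to every axial slice."""
    cfg = cfg or SkinConfig()
    out = np.zeros(vol.shape, dtype=np.uint8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(vol.shape[0]):
            out[k] = segment_skin_slice(vol.data[k], cfg)
    return BinaryVolume(out, vol.spacing, vol.origin)
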