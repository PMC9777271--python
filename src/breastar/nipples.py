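"""Gradient-based nipple localization on skin-mask contours.

On each axial slice the anterior skin profile is extracted (the
anterior-most mask pixel per image column, supine convention: anterior
at low row index). Local slope angles theta = atan(dh/dx) of the
profile height h are smoothed with a moving average, and every maximal
section where theta passes from positive (rising toward an apex)
through zero to negative (falling) becomes a nipple candidate. When a
side carries several candidates, mirror ("virtual") candidates across
the body centre let all pairings be scored by profile symmetry, and
the most symmetric pair wins. Per-slice detections are fused across a
central band of slices by a column-vote: the apex slice is the median
of the slices voting for the winning column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryVolume, voxel_to_world

__all__ = [
    "Contour",
    "NippleCandidate",
    "NipplePair",
    "NippleConfig",
    "DetectionError",
    "anterior_contour",
    "contour_gradients",
    "find_candidates",
    "select_pair",
    "detect_nipples",
]


class DetectionError(RuntimeError):
    """No nipple candidate could be found."""


@dataclass
class Contour:
    """Anterior profile of one slice: per-column apex pixels, left to right.

    ``height`` is the anterior extent (larger = more anterior), i.e.
    ``-row`` under the default anterior-up convention, so that rising
    slopes have positive theta.
    """

    x: np.ndarray
    y: np.ndarray
    z: int = 0
    theta: np.ndarray | None = None

    @property
    def height(self) -> np.ndarray:
        return -self.y.astype(float)

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class NippleCandidate:
    apex_x: float
    apex_y: float
    z: int
    extent: tuple[int, int]  # [start, stop) contour indices of the section
    prominence: float  # apex height above the section endpoints' mean
    theta_profile: np.ndarray = field(repr=False, default=None)
    virtual: bool = False


@dataclass
class NipplePair:
    """Final left/right nipple positions in world millimetres."""

    left: np.ndarray
    right: np.ndarray
    score: float = 0.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float).reshape(3)
        self.right = np.asarray(self.right, dtype=float).reshape(3)
        if self.left[0] >= self.right[0]:
            raise ValueError(
                "left nipple must have smaller world x than right (supine convention)"
            )


@dataclass
class NippleConfig:
    smoothing_window: int = 5
    z_band: float = 0.6  # central fraction of slices searched
    min_prominence: float = 2.0  # pixels
    column_tolerance: int = 6  # pixels, for cross-slice column clustering
    height_tolerance: float = 3.0  # pixels; a slice votes for a nipple only
    # if its apex comes within this of the cluster's anterior extreme
    anterior_is_low_row: bool = True


def anterior_contour(mask: np.ndarray, z: int = 0, anterior_is_low_row: bool = True) -> Contour:
    """Anterior-most foreground pixel of each occupied column, ordered by x."""
    m = np.asarray(mask) > 0
    if not anterior_is_low_row:
        m = m[::-1]
    cols = np.where(m.any(axis=0))[0]
    if len(cols) == 0:
        return Contour(x=np.empty(0, int), y=np.empty(0, int), z=z)
    rows = m[:, cols].argmax(axis=0)  # first True per column = minimum row
    if not anterior_is_low_row:
        rows = mask.shape[0] - 1 - rows
    return Contour(x=cols.astype(int), y=rows.astype(int), z=z)


def contour_gradients(contour: Contour, window: int = 5) -> Contour:
    """Fill ``theta`` with smoothed local slope angles of the profile.

    theta_i = atan(dh / dx) between consecutive contour points, then a
    centred moving average over ``window`` points damps pixelation
    noise. The angle at index i describes the slope arriving at point i.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if len(contour) < 2:
        raise ValueError("contour needs at least 2 points to compute gradients")
    dh = np.diff(contour.height)
    dx = np.diff(contour.x.astype(float))
    raw = np.arctan2(dh, dx)  # dx > 0 by construction, so range (-pi/2, pi/2)
    raw = np.concatenate([[raw[0]], raw])  # align to points
    if window > 1:
        pad = window // 2
        padded = np.pad(raw, pad, mode="edge")
        kernel = np.ones(window) / window
        theta = np.convolve(padded, kernel, mode="valid")
    else:
        theta = raw
    return Contour(x=contour.x, y=contour.y, z=contour.z, theta=theta)


def find_candidates(contour: Contour, min_prominence: float = 0.0) -> list[NippleCandidate]:
    """Sections where theta shifts from increment to decrement.

    Each positive-to-negative zero crossing of theta spawns a candidate:
    the section extends left while theta stays positive and right while
    it stays negative; the apex is the most anterior point inside, and
    the prominence is the apex height above the mean endpoint height.
    """
    if contour.theta is None:
        raise ValueError("run contour_gradients first")
    theta = contour.theta
    h = contour.height
    n = len(theta)
    out: list[NippleCandidate] = []
    i = 1
    while i < n:
        if theta[i - 1] > 0 and theta[i] <= 0:
            start = i - 1
            while start > 0 and theta[start - 1] > 0:
                start -= 1
            stop = i
            while stop < n - 1 and theta[stop + 1] < 0:
                stop += 1
            seg = slice(start, stop + 1)
            hseg = h[seg]
            # rasterization flattens the tip into a plateau; take its middle
            top = np.flatnonzero(hseg == hseg.max())
            apex = start + int(round(top.mean()))
            prominence = h[apex] - 0.5 * (h[start] + h[stop])
            if prominence >= min_prominence:
                out.append(
                    NippleCandidate(
                        apex_x=float(contour.x[apex]),
                        apex_y=float(contour.y[apex]),
                        z=contour.z,
                        extent=(start, stop + 1),
                        prominence=float(prominence),
                        theta_profile=theta[seg].copy(),
                    )
                )
            i = stop + 1
        else:
            i += 1
    return out


def _mirror(c: NippleCandidate, center_x: float) -> NippleCandidate:
    return NippleCandidate(
        apex_x=2 * center_x - c.apex_x,
        apex_y=c.apex_y,
        z=c.z,
        extent=c.extent,
        prominence=c.prominence,
        theta_profile=-c.theta_profile[::-1],
        virtual=True,
    )


def _pair_score(left: NippleCandidate, right: NippleCandidate, ref_len: int,
                center_x: float, width: float) -> float:
    """Symmetry score of a left/right pairing (larger = more symmetric).

    The right profile is mirrored (reversed, negated) and both are
    resampled to the reference (tallest-candidate) section length; the
    score is the negated mean absolute gradient difference, plus
    penalties on apex asymmetry about the body centre and on apex
    height (anterior extent) disagreement — nipples sit at matching
    heights on the two breasts, while a mound shoulder paired with a
    true tip does not.
    """
    grid = np.linspace(0.0, 1.0, max(ref_len, 2))

    def resample(profile: np.ndarray) -> np.ndarray:
        src = np.linspace(0.0, 1.0, len(profile)) if len(profile) > 1 else np.array([0.0])
        return np.interp(grid, src, profile)

    lp = resample(left.theta_profile)
    rp = resample(-right.theta_profile[::-1])  # mirror the right section
    mismatch = float(np.abs(lp - rp).mean())
    asym = abs((2 * center_x - right.apex_x) - left.apex_x) / max(width, 1.0)
    height_mismatch = abs(left.apex_y - right.apex_y) / max(0.1 * width, 1.0)
    return -(mismatch + asym + height_mismatch)


def select_pair(
    candidates: list[NippleCandidate], center_x: float, width: float | None = None
) -> tuple[NippleCandidate, NippleCandidate, float]:
    """Choose the left/right candidate pair by symmetry about ``center_x``.

    Candidates are split by side; a side with no real candidate is
    populated with mirrors of the other side's candidates (virtual
    candidates), so pairings always exist. All real-real pairings are
    scored (real-virtual only when a side is empty); the pair with the
    largest symmetry score wins. With exactly one candidate per side
    that pair is returned directly.
    """
    left = [c for c in candidates if c.apex_x < center_x and not c.virtual]
    right = [c for c in candidates if c.apex_x >= center_x and not c.virtual]
    if not left and not right:
        raise DetectionError("no nipple candidates on either side")
    width = width or 2 * center_x
    if not left:
        left = [_mirror(c, center_x) for c in right]
    if not right:
        right = [_mirror(c, center_x) for c in left]
    if len(left) == 1 and len(right) == 1:
        return left[0], right[0], 0.0
    ref_len = max(
        c.extent[1] - c.extent[0] for c in left + right
    )  # tallest region sets the comparison length
    best = None
    for lc in left:
        for rc in right:
            if lc.virtual and rc.virtual:
                continue
            s = _pair_score(lc, rc, ref_len, center_x, width)
            if best is None or s > best[2]:
                best = (lc, rc, s)
    assert best is not None
    return best


def _slice_center_x(mask_slice: np.ndarray) -> float:
    cols = np.where((np.asarray(mask_slice) > 0).any(axis=0))[0]
    return 0.5 * (cols.min() + cols.max())


def _cluster_candidates(
    cands: list[NippleCandidate], cfg: NippleConfig
) -> list[NippleCandidate]:
    """Fuse per-slice candidates of one side into column clusters.

    Candidates are assigned (in order of decreasing anterior height) to
    the first cluster whose reference column is within the column
    tolerance. Each cluster is summarized by its most anterior member
    — the nipple tip — except that its slice index becomes the median
    of the member slices whose apex reaches within ``height_tolerance``
    of the tip ("the middle of the slices where the nipple is
    present"); slices where the contour bump is present but well below
    the tip belong to the breast mound, not the nipple, and do not vote.
    """
    sign = 1.0 if cfg.anterior_is_low_row else -1.0
    ordered = sorted(cands, key=lambda c: sign * c.apex_y)  # most anterior first
    clusters: list[list[NippleCandidate]] = []
    for c in ordered:
        for cl in clusters:
            if abs(c.apex_x - cl[0].apex_x) <= cfg.column_tolerance:
                cl.append(c)
                break
        else:
            clusters.append([c])
    reps = []
    for cl in clusters:
        tip = cl[0]
        votes = [
            m.z for m in cl if sign * (m.apex_y - tip.apex_y) <= cfg.height_tolerance
        ]
        reps.append(
            NippleCandidate(
                apex_x=tip.apex_x,
                apex_y=tip.apex_y,
                z=int(np.median(votes)),
                extent=tip.extent,
                prominence=tip.prominence,
                theta_profile=tip.theta_profile,
            )
        )
    return reps


def detect_nipples(skin: BinaryVolume, cfg: NippleConfig | None = None) -> NipplePair:
    """Locate both nipples on a skin mask; returns world-mm coordinates.

    Candidates are collected on every slice of a central z-band,
    clustered per side into candidate columns, each cluster fused
    across slices (apex = anterior extreme, slice = median of the
    voting slices), and the final left/right pair is chosen from the
    cluster representatives by the symmetry score of
    :func:`select_pair`.
    """
    cfg = cfg or NippleConfig()
    nz = skin.shape[0]
    half_band = int(round(nz * cfg.z_band / 2))
    k0, k1 = max(0, nz // 2 - half_band), min(nz, nz // 2 + half_band + 1)
    all_cands: list[NippleCandidate] = []
    centers, widths = [], []
    for k in range(k0, k1):
        sl = skin.data[k]
        if not sl.any():
            continue
        contour = anterior_contour(sl, z=k, anterior_is_low_row=cfg.anterior_is_low_row)
        if len(contour) < 2:
            continue
        contour = contour_gradients(contour, cfg.smoothing_window)
        all_cands.extend(find_candidates(contour, cfg.min_prominence))
        centers.append(_slice_center_x(sl))
        widths.append(float(len(contour)))
    if not all_cands:
        raise DetectionError("no slice produced a nipple candidate")
    center_x = float(np.median(centers))
    width = float(np.median(widths))
    left = _cluster_candidates([c for c in all_cands if c.apex_x < center_x], cfg)
    right = _cluster_candidates([c for c in all_cands if c.apex_x >= center_x], cfg)
    lc, rc, _ = select_pair(left + right, center_x, width=width)
    left_w = voxel_to_world(
        np.array([lc.z, lc.apex_y, lc.apex_x], dtype=float), skin.spacing, skin.origin
    )
    right_w = voxel_to_world(
        np.array([rc.z, rc.apex_y, rc.apex_x], dtype=float), skin.spacing, skin.origin
    )
    if left_w[0] > right_w[0]:
        left_w, right_w = right_w, left_w
    return NipplePair(left=left_w, right=right_w)
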