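"""Anterior-contour extraction, gradient candidates and nipple pairing."""

import numpy as np
import pytest

from breastar.core import BinaryVolume
from breastar.nipples import (
    DetectionError,
    NippleConfig,
    anterior_contour,
    contour_gradients,
    detect_nipples,
    find_candidates,
    select_pair,
)
from breastar.phantom import PhantomSpec, generate_ct


def bump_mask(n=128, bumps=((40, 18, 10),), base_row=90):
    """Mask whose anterior profile is base_row minus Gaussian bumps
    (centre, amplitude, sigma per bump)."""
    cols = np.arange(n)
    profile = np.full(n, float(base_row))
    for c, a, s in bumps:
        profile -= a * np.exp(-((cols - c) ** 2) / (2 * s**2))
    mask = np.zeros((n, n), dtype=np.uint8)
    for x in range(n):
        mask[int(round(profile[x])) :, x] = 1
    return mask


class TestAnteriorContour:
    def test_rectangle_gives_flat_contour(self):
        mask = np.zeros((20, 30), dtype=np.uint8)
        mask[5:15, :] = 1
        c = anterior_contour(mask)
        assert np.array_equal(c.y, np.full(30, 5))
        assert np.all(np.diff(c.x) > 0)

    def test_semicircle_matches_analytic_rows(self):
        n, r, cx = 64, 25, 32
        yy, xx = np.mgrid[0:n, 0:n]
        mask = ((np.hypot(yy - 60, xx - cx) <= r) & (yy <= 60)).astype(np.uint8)
        c = anterior_contour(mask)
        for x, y in zip(c.x, c.y):
            expected = 60 - np.sqrt(r**2 - (x - cx) ** 2)
            assert abs(y - expected) <= 1.0

    def test_empty_mask_gives_empty_contour(self):
        assert len(anterior_contour(np.zeros((5, 5), dtype=np.uint8))) == 0


class TestContourGradients:
    def test_flat_contour_has_zero_theta(self):
        mask = np.zeros((10, 20), dtype=np.uint8)
        mask[4:, :] = 1
        c = contour_gradients(anterior_contour(mask), window=5)
        assert np.allclose(c.theta, 0.0)

    def test_forty_five_degree_ramp(self):
        # profile rising one row per column -> theta = atan(1) = pi/4
        n = 20
        mask = np.zeros((n + 2, n), dtype=np.uint8)
        for x in range(n):
            mask[n - x :, x] = 1
        c = contour_gradients(anterior_contour(mask), window=1)
        assert np.allclose(c.theta[1:], np.pi / 4)

    def test_window_average_matches_brute_force(self, rng):
        mask = bump_mask(n=64, bumps=((32, 15, 8),), base_row=45)
        raw = contour_gradients(anterior_contour(mask), window=1)
        smoothed = contour_gradients(anterior_contour(mask), window=3)
        padded = np.pad(raw.theta, 1, mode="edge")
        expected = np.array([padded[i : i + 3].mean() for i in range(len(raw.theta))])
        assert np.allclose(smoothed.theta, expected, atol=1e-12)

    def test_too_short_contour_rejected(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        with pytest.raises(ValueError, match="2 points"):
            contour_gradients(anterior_contour(mask))

    def test_even_window_rejected(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[4:, :] = 1
        with pytest.raises(ValueError, match="odd"):
            contour_gradients(anterior_contour(mask), window=4)


class TestFindCandidates:
    def test_single_bump_yields_single_candidate_at_apex(self):
        mask = bump_mask(bumps=((40, 18, 10),))
        c = contour_gradients(anterior_contour(mask), window=5)
        cands = find_candidates(c, min_prominence=2.0)
        assert len(cands) == 1
        assert abs(cands[0].apex_x - 40) <= 1

    def test_flat_contour_yields_nothing(self):
        mask = np.zeros((10, 30), dtype=np.uint8)
        mask[4:, :] = 1
        c = contour_gradients(anterior_contour(mask), window=5)
        assert find_candidates(c) == []

    def test_two_bumps_yield_two_candidates(self):
        mask = bump_mask(bumps=((35, 18, 8), (90, 18, 8)))
        c = contour_gradients(anterior_contour(mask), window=5)
        cands = find_candidates(c, min_prominence=2.0)
        assert len(cands) == 2
        xs = sorted(cand.apex_x for cand in cands)
        assert abs(xs[0] - 35) <= 1 and abs(xs[1] - 90) <= 1


class TestSelectPair:
    def _candidates(self, bumps, n=128):
        mask = bump_mask(n=n, bumps=bumps)
        c = contour_gradients(anterior_contour(mask), window=5)
        return find_candidates(c, min_prominence=2.0), mask

    def test_one_candidate_per_side_forced(self):
        cands, _ = self._candidates(((35, 18, 8), (90, 12, 6)))
        lc, rc, _ = select_pair(cands, center_x=64.0)
        assert lc.apex_x < 64 <= rc.apex_x

    def test_symmetric_pair_midpoint(self):
        cands, _ = self._candidates(((40, 18, 8), (88, 18, 8)))
        lc, rc, _ = select_pair(cands, center_x=64.0)
        assert abs(lc.apex_x + rc.apex_x - 2 * 64.0) <= 2.0

    def test_mirror_consistent_left_chosen_among_two(self):
        # two left bumps; the one mirroring the right bump (same shape,
        # symmetric position) must win over the narrow decoy
        cands, _ = self._candidates(((14, 10, 4), (40, 18, 8), (88, 18, 8)))
        assert len(cands) == 3
        lc, rc, _ = select_pair(cands, center_x=64.0)
        assert abs((2 * 64.0 - rc.apex_x) - lc.apex_x) <= 3.0

    def test_selection_matches_exhaustive_scoring(self):
        from breastar.nipples import _pair_score

        cands, _ = self._candidates(((14, 10, 4), (40, 18, 8), (78, 12, 4), (100, 18, 8)))
        lc, rc, score = select_pair(cands, center_x=64.0, width=128.0)
        left = [c for c in cands if c.apex_x < 64]
        right = [c for c in cands if c.apex_x >= 64]
        assert len(left) == 2 and len(right) == 2
        ref_len = max(c.extent[1] - c.extent[0] for c in cands)
        best = max(
            ((l, r, _pair_score(l, r, ref_len, 64.0, 128.0)) for l in left for r in right),
            key=lambda t: t[2],
        )
        assert (lc.apex_x, rc.apex_x) == (best[0].apex_x, best[1].apex_x)
        assert np.isclose(score, best[2])

    def test_single_side_uses_virtual_mirror(self):
        cands, _ = self._candidates(((40, 18, 8),))
        lc, rc, _ = select_pair(cands, center_x=64.0)
        assert rc.virtual and not lc.virtual
        assert np.isclose(rc.apex_x, 2 * 64.0 - lc.apex_x)

    def test_no_candidates_raises(self):
        with pytest.raises(DetectionError):
            select_pair([], center_x=64.0)


class TestDetectNipples:
    def test_recovers_truth_on_default_phantom(self, default_phantom):
        _, truth = default_phantom
        pred = detect_nipples(truth.skin_mask, NippleConfig())
        err = 0.5 * (
            np.linalg.norm(pred.left - truth.nipples.left)
            + np.linalg.norm(pred.right - truth.nipples.right)
        )
        assert err <= 3.0

    def test_translation_equivariance_in_plane(self, default_phantom):
        _, truth = default_phantom
        base = detect_nipples(truth.skin_mask, NippleConfig())
        shifted = np.roll(truth.skin_mask.data, 10, axis=2)  # +10 voxels in x
        moved = detect_nipples(
            BinaryVolume(shifted, truth.skin_mask.spacing, truth.skin_mask.origin),
            NippleConfig(),
        )
        assert np.allclose(moved.left - base.left, [10.0, 0.0, 0.0])
        assert np.allclose(moved.right - base.right, [10.0, 0.0, 0.0])

    def test_mask_without_protrusions_fails_loudly(self):
        flat = np.zeros((20, 32, 32), dtype=np.uint8)
        flat[:, 16:, :] = 1
        with pytest.raises(DetectionError):
            detect_nipples(BinaryVolume(flat), NippleConfig())

    def test_symmetric_phantom_detection_is_symmetric(self):
        spec = PhantomSpec(noise_sigma=0.0, pad=False)
        _, truth = generate_ct(spec)
        pred = detect_nipples(truth.skin_mask, NippleConfig())
        centre = spec.torso_center_x
        assert abs((pred.left[0] + pred.right[0]) - 2 * centre) <= 2.0
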