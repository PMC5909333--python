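"""Remote-referenced thresholding and enclosed no-flow detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from nfmri.geometry import circle_polygon
from nfmri.io import ContourSet, ContourValidationError
from nfmri.phantom import render_lge_series
from nfmri.segmentation import (MaskInvariantError, RegionMasks, classify_enhanced,
                                detect_nf, enhancement_threshold, myocardium_mask,
                                nf_from_manual_contour, remote_stats, segment_lge)


class TestThreshold:
    @pytest.mark.parametrize("mean, sd, k, expected", [
        (100.0, 10.0, 5.0, 150.0),
        (100.0, 0.0, 5.0, 100.0),
        (57.3, 4.2, 5.0, 78.3),
    ])
    def test_mean_plus_k_sd(self, mean, sd, k, expected):
        assert enhancement_threshold(mean, sd, k) == pytest.approx(expected)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            enhancement_threshold(100.0, -1.0)

    def test_pixel_exactly_at_threshold_not_enhanced(self):
        img = np.array([[149.9, 150.0, 150.1]])
        myo = np.ones_like(img, dtype=bool)
        out = classify_enhanced(img, myo, 150.0)
        assert out.tolist() == [[False, False, True]]

    def test_matches_brute_force_comparison(self):
        rng = np.random.default_rng(3)
        img = rng.normal(100, 30, (32, 32))
        myo = rng.random((32, 32)) > 0.4
        out = classify_enhanced(img, myo, 120.0)
        oracle = np.array([[myo[r, c] and img[r, c] > 120.0 for c in range(32)]
                           for r in range(32)])
        np.testing.assert_array_equal(out, oracle)

    @settings(max_examples=30, derandomize=True)
    @given(k_lo=st.floats(0.0, 10.0), dk=st.floats(0.0, 10.0))
    def test_raising_k_never_grows_enhanced(self, k_lo, dk):
        rng = np.random.default_rng(9)
        img = rng.normal(100, 25, (24, 24))
        myo = np.ones((24, 24), dtype=bool)
        lo = classify_enhanced(img, myo, enhancement_threshold(100.0, 10.0, k_lo))
        hi = classify_enhanced(img, myo, enhancement_threshold(100.0, 10.0, k_lo + dk))
        assert not np.any(hi & ~lo)


class TestRemoteStats:
    def test_uniform_roi(self):
        img = np.full((10, 10), 100.0)
        mean, sd, n = remote_stats(img, np.ones_like(img, dtype=bool))
        assert (mean, sd, n) == (100.0, 0.0, 100)

    def test_fewer_than_100_pixels_is_hard_error(self):
        img = np.zeros((10, 10))
        mask = np.zeros_like(img, dtype=bool)
        mask.ravel()[:99] = True
        with pytest.raises(ValueError, match="at least 100"):
            remote_stats(img, mask)

    def test_agrees_with_direct_summation(self):
        rng = np.random.default_rng(17)
        img = rng.normal(80, 12, (20, 20))
        mask = np.zeros_like(img, dtype=bool)
        mask[:10] = True
        mean, sd, n = remote_stats(img, mask)
        vals = [img[r, c] for r in range(20) for c in range(20) if mask[r, c]]
        m = sum(vals) / len(vals)
        s = (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert mean == pytest.approx(m, rel=1e-12)
        assert sd == pytest.approx(s, rel=1e-12)
        assert n == 200


class TestMyocardiumMask:
    def test_concentric_circles_match_pixel_centre_oracle(self):
        cs = ContourSet(slices=[{"endo": circle_polygon((32, 32), 20.0),
                                 "epi": circle_polygon((32, 32), 30.0),
                                 "remote": circle_polygon((32, 50), 3.0)}])
        mask = myocardium_mask(cs, (64, 64), (1.0, 1.0))
        # independent oracle: even-odd crossing test against both polygons
        def crossings(poly, px, py):
            hit = False
            for i in range(len(poly)):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % len(poly)]
                if (y1 > py) != (y2 > py) and px < x1 + (py - y1) * (x2 - x1) / (y2 - y1):
                    hit = not hit
            return hit
        endo, epi = cs.slices[0]["endo"], cs.slices[0]["epi"]
        oracle = np.array([[crossings(epi, c + 0.5, r + 0.5)
                            and not crossings(endo, c + 0.5, r + 0.5)
                            for c in range(64)] for r in range(64)])
        np.testing.assert_array_equal(mask[0], oracle)
        assert mask.sum() == pytest.approx(np.pi * (30**2 - 20**2), rel=0.02)

    def test_equal_contours_give_empty_mask(self):
        ring = circle_polygon((25, 25), 20.0)
        cs = ContourSet(slices=[{"endo": ring, "epi": ring.copy()}])
        assert myocardium_mask(cs, (64, 64), (1.0, 1.0)).sum() == 0

    def test_missing_contour_names_slice(self):
        cs = ContourSet(slices=[{"epi": circle_polygon((25, 25), 20.0)}])
        with pytest.raises(ContourValidationError, match="slice 0.*endo"):
            myocardium_mask(cs, (64, 64), (1.0, 1.0))

    def test_phantom_contours_reproduce_truth_mask(self, small_truth, small_spec):
        mask = myocardium_mask(small_truth.contours, (small_spec.n_rows, small_spec.n_cols),
                               small_spec.pixel_spacing_mm)
        np.testing.assert_array_equal(mask, small_truth.myocardium_mask)


def _island_scene():
    """11x11 myocardium block with an enhanced wall enclosing holes."""
    myo = np.zeros((11, 11), dtype=bool)
    myo[1:-1, 1:-1] = True
    enhanced = myo.copy()
    return myo, enhanced


class TestDetectNf:
    def test_enclosed_hole_is_returned(self):
        myo, enhanced = _island_scene()
        enhanced[5, 5] = False
        nf = detect_nf(np.zeros_like(myo, float), myo, enhanced, 0.0)
        assert nf[5, 5] and nf.sum() == 1

    def test_region_contiguous_with_remote_is_excluded(self):
        myo, enhanced = _island_scene()
        enhanced[5, 5:] = False  # channel reaching the myocardium edge
        nf = detect_nf(np.zeros_like(myo, float), myo, enhanced, 0.0)
        assert nf.sum() == 0

    def test_diagonal_islands_enclose_each_other(self):
        # regression: diagonally-adjacent single-pixel holes are all enclosed
        myo, enhanced = _island_scene()
        for rc in ((4, 4), (5, 5), (6, 6)):
            enhanced[rc] = False
        nf = detect_nf(np.zeros_like(myo, float), myo, enhanced, 0.0)
        assert nf.sum() == 3

    def test_diagonal_chain_to_remote_is_excluded(self):
        myo, enhanced = _island_scene()
        enhanced[5, 5] = False
        enhanced[4, 6] = False
        enhanced[3, 7] = False
        enhanced[2, 8] = False
        enhanced[1, 9] = False  # touches the myocardium boundary pixel ring
        enhanced[1:3, 1:4] = False  # a genuinely remote corner region
        nf = detect_nf(np.zeros_like(myo, float), myo, enhanced, 0.0)
        # the corner region touches background -> outside; the chain links
        # each touch the next outside component -> all excluded
        assert not nf[1, 9] and not nf[1, 1]

    def test_empty_nf_is_valid(self):
        myo, enhanced = _island_scene()
        nf = detect_nf(np.zeros_like(myo, float), myo, enhanced, 0.0)
        assert nf.sum() == 0

    def test_enhanced_outside_myocardium_rejected(self):
        myo, enhanced = _island_scene()
        enhanced[0, 0] = True
        with pytest.raises(ValueError, match="within the myocardium"):
            detect_nf(np.zeros_like(myo, float), myo, enhanced, 0.0)


class TestSegmentPipeline:
    def test_total_mi_is_union_and_disjoint(self, small_truth):
        series = render_lge_series(small_truth, 2.0)
        masks = segment_lge(series, small_truth.contours)
        assert not np.any(masks.enhanced & masks.nf)
        np.testing.assert_array_equal(masks.total_mi, masks.enhanced | masks.nf)
        # indirect measurement identity: area(total) - area(enhanced) = area(nf)
        assert masks.total_mi.sum() - masks.enhanced.sum() == masks.nf.sum()

    def test_recovers_truth_masks_at_default_snr(self, small_truth):
        series = render_lge_series(small_truth, 2.0)
        masks = segment_lge(series, small_truth.contours)
        mismatch = np.logical_xor(masks.nf, small_truth.nf_masks[2.0]).sum()
        assert mismatch <= 0.05 * small_truth.nf_masks[2.0].sum()
        mismatch_mi = np.logical_xor(masks.total_mi, small_truth.mi_mask).sum()
        assert mismatch_mi <= 0.05 * small_truth.mi_mask.sum()

    def test_manual_contour_path_matches_detection(self, small_truth):
        series = render_lge_series(small_truth, 2.0)
        auto = segment_lge(series, small_truth.contours)
        manual = segment_lge(series, small_truth.contours, manual_nf=True)
        # agreement within a one-pixel boundary band of the truth core
        band = np.zeros_like(auto.nf)
        for s in range(band.shape[0]):
            t = small_truth.nf_masks[2.0][s]
            band[s] = ndimage.binary_dilation(t, np.ones((3, 3), bool)) & ~ndimage.binary_erosion(t, np.ones((3, 3), bool))
        diff = np.logical_xor(auto.nf, manual.nf)
        assert np.all(band[diff])

    def test_manual_overlap_with_enhanced_clips_and_warns(self):
        myo = np.zeros((20, 20), dtype=bool)
        myo[2:18, 2:18] = True
        enhanced = np.zeros_like(myo)
        enhanced[5:15, 5:15] = True
        square = np.array([[4.0, 4.0], [9.0, 4.0], [9.0, 9.0], [4.0, 9.0]])
        cs = ContourSet(slices=[{"nf": square}])
        with pytest.warns(UserWarning, match="overlaps"):
            nf = nf_from_manual_contour(cs, 0, (20, 20), (1.0, 1.0), myo, enhanced)
        assert not np.any(nf & enhanced)
        assert nf.sum() > 0

    def test_assembly_rejects_small_remote_roi(self):
        myo = np.ones((1, 20, 20), dtype=bool)
        remote = np.zeros_like(myo)
        remote[0, 0, :5] = True
        with pytest.raises(MaskInvariantError, match="at least 100"):
            RegionMasks(myocardium=myo, remote=remote,
                        enhanced=np.zeros_like(myo), nf=np.zeros_like(myo),
                        remote_mean=np.zeros(1), remote_sd=np.zeros(1),
                        threshold=np.zeros(1), pixel_spacing_mm=(1.0, 1.0),
                        slice_thickness_mm=10.0)

    def test_assembly_rejects_overlapping_partitions(self):
        myo = np.ones((1, 20, 20), dtype=bool)
        remote = np.zeros_like(myo)
        remote[0, :10] = True
        bad = np.zeros_like(myo)
        bad[0, 12:14] = True
        with pytest.raises(MaskInvariantError, match="disjoint"):
            RegionMasks(myocardium=myo, remote=remote, enhanced=bad, nf=bad,
                        remote_mean=np.zeros(1), remote_sd=np.zeros(1),
                        threshold=np.zeros(1), pixel_spacing_mm=(1.0, 1.0),
                        slice_thickness_mm=10.0)

    @pytest.mark.parametrize("k_pair", [(3.0, 5.0), (5.0, 8.0)])
    def test_threshold_monotone_in_k_on_phantom(self, small_truth, k_pair):
        series = render_lge_series(small_truth, 2.0)
        lo = segment_lge(series, small_truth.contours, k=k_pair[0])
        hi = segment_lge(series, small_truth.contours, k=k_pair[1])
        assert not np.any(hi.enhanced & ~lo.enhanced)
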