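"""Smoothing, nucleus/foci watershed segmentation, and GFP gating."""

import numpy as np
import pytest
from skimage.morphology import disk

from chromoquant import (
    FociParams,
    SegmentationParams,
    classify_gfp,
    score_segmentation,
    segment_foci,
    segment_nuclei,
    smooth_image,
)
from chromoquant.segmentation import LabelMap


def _disk_mean_oracle(img, radius):
    """Brute-force per-pixel disk mean with edge-repeating reflective
    padding (the convention smooth_image documents)."""
    fp = disk(radius).astype(bool)
    pad = np.pad(img.astype(float), radius, mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            window = pad[r : r + 2 * radius + 1, c : c + 2 * radius + 1]
            out[r, c] = window[fp].mean()
    return out


class TestSmoothImage:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 5.0)
        assert np.allclose(smooth_image(img, 3), 5.0)

    def test_single_bright_pixel_spreads_by_disk_size(self):
        img = np.zeros((11, 11))
        img[5, 5] = 130.0
        out = smooth_image(img, 2)
        n = int(disk(2).sum())  # 13 pixels
        assert out[5, 5] == pytest.approx(130.0 / n)
        assert out[5, 7] == pytest.approx(130.0 / n)  # disk member
        assert out[5, 8] == 0.0  # outside the disk

    def test_matches_brute_force_disk_mean(self, rng):
        img = rng.random((16, 16)) * 100
        assert np.allclose(smooth_image(img, 2), _disk_mean_oracle(img, 2))

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            smooth_image(np.zeros((5, 5)), 10)


def _gaussian_disk(shape, center, sigma, amp):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return amp * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


class TestSegmentNuclei:
    def test_all_zero_image_gives_no_objects(self):
        lm = segment_nuclei(np.zeros((32, 32)), SegmentationParams())
        assert lm.n_objects == 0

    def test_two_disjoint_nuclei_recovered(self):
        img = _gaussian_disk((64, 64), (18, 18), 6, 200) + _gaussian_disk(
            (64, 64), (45, 45), 6, 200
        )
        lm = segment_nuclei(img, SegmentationParams(min_nucleus_area_px=10))
        assert lm.n_objects == 2
        # each truth disk covered >= 90% by exactly one label
        rr, cc = np.ogrid[:64, :64]
        for center in [(18, 18), (45, 45)]:
            truth = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= 5**2
            labels_in = lm.labels[truth]
            best = np.bincount(labels_in).argmax()
            assert best > 0
            assert (labels_in == best).mean() >= 0.9

    def test_touching_nuclei_split_by_watershed(self):
        # two peaks whose smoothed profile keeps two h-maxima
        img = _gaussian_disk((48, 64), (24, 22), 5, 200) + _gaussian_disk(
            (48, 64), (24, 40), 5, 200
        )
        lm = segment_nuclei(img, SegmentationParams(min_nucleus_area_px=10))
        assert lm.n_objects == 2
        # the two centres fall in different labels
        assert lm.labels[24, 22] != lm.labels[24, 40]
        assert lm.labels[24, 22] > 0 and lm.labels[24, 40] > 0

    def test_non_finite_pixels_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            segment_nuclei(img, SegmentationParams())

    def test_border_touching_nuclei_dropped_by_default(self):
        img = _gaussian_disk((40, 40), (2, 20), 6, 200)
        params = SegmentationParams(min_nucleus_area_px=5)
        lm = segment_nuclei(img, params)
        assert lm.n_objects == 0
        keep = SegmentationParams(min_nucleus_area_px=5, exclude_border=False)
        assert segment_nuclei(img, keep).n_objects == 1

    def test_shift_invariance_with_explicit_thresholds(self):
        """Adding a constant to the image and to fg_threshold (with fixed h)
        leaves the label map unchanged."""
        img = _gaussian_disk((48, 48), (24, 24), 6, 200)
        p1 = SegmentationParams(fg_threshold=50.0, h=20.0, min_nucleus_area_px=10)
        p2 = SegmentationParams(fg_threshold=80.0, h=20.0, min_nucleus_area_px=10)
        lm1 = segment_nuclei(img, p1)
        lm2 = segment_nuclei(img + 30.0, p2)
        assert np.array_equal(lm1.labels, lm2.labels)

    def test_deterministic_bitwise(self, small_field):
        from chromoquant import max_project

        _, stack, _ = small_field
        dapi = max_project(stack, "dapi")
        a = segment_nuclei(dapi, SegmentationParams())
        b = segment_nuclei(dapi, SegmentationParams())
        assert np.array_equal(a.labels, b.labels)

    def test_generator_field_recall_precision(self, segmented_field):
        _, _, truth, _, _, nuclei, _ = segmented_field
        score = score_segmentation(nuclei, truth, "nuclei")
        assert score.precision >= 0.95
        assert score.recall >= 0.95


class TestClassifyGfp:
    def _one_nucleus(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:6, 2:6] = 1
        return LabelMap(labels, 1)

    def test_constant_high_gfp_positive(self):
        nuclei = self._one_nucleus()
        comp = np.full((10, 10), 100.0)
        assert classify_gfp(nuclei, comp, 50.0) == {1: "positive"}

    def test_zero_gfp_negative(self):
        nuclei = self._one_nucleus()
        assert classify_gfp(nuclei, np.zeros((10, 10)), 50.0) == {1: "negative"}

    def test_threshold_is_inclusive_on_the_mean(self):
        """Half the nucleus at 0, half at 100: mean is exactly the threshold
        and the call is positive (>= is inclusive)."""
        nuclei = self._one_nucleus()
        comp = np.zeros((10, 10))
        comp[2:6, 4:6] = 100.0  # half the 4x4 nucleus
        # oracle: explicit pixel sum
        mask = nuclei.labels == 1
        assert comp[mask].sum() / mask.sum() == 50.0
        assert classify_gfp(nuclei, comp, 50.0) == {1: "positive"}

    def test_shape_mismatch_rejected(self):
        nuclei = self._one_nucleus()
        with pytest.raises(ValueError, match="shape"):
            classify_gfp(nuclei, np.zeros((5, 5)), 50.0)


class TestSegmentFoci:
    def _nucleus_map(self, shape=(40, 40), box=(5, 35)):
        labels = np.zeros(shape, dtype=np.int32)
        labels[box[0] : box[1], box[0] : box[1]] = 1
        return LabelMap(labels, 1)

    def test_uniform_signal_below_threshold_gives_no_foci(self):
        nuclei = self._nucleus_map()
        mark = np.full((40, 40), 3.0)
        foci = segment_foci(mark, nuclei, FociParams(focus_threshold=10.0, focus_h=1.0))
        assert foci.n_objects == 0

    def test_single_punctum_recovered_with_centroid(self):
        nuclei = self._nucleus_map()
        mark = _gaussian_disk((40, 40), (20, 17), 2, 150) + 5.0
        foci = segment_foci(mark, nuclei, FociParams())
        assert foci.n_objects == 1
        rows, cols = np.nonzero(foci.labels == 1)
        assert abs(rows.mean() - 20) <= 1 and abs(cols.mean() - 17) <= 1
        assert foci.owners == {1: 1}

    def test_focus_pixels_stay_inside_their_nucleus(self, segmented_field):
        _, _, _, _, _, nuclei, foci = segmented_field
        assert foci.n_objects > 0
        for lab, owner in foci.owners.items():
            owners_of_pixels = nuclei.labels[foci.labels == lab]
            assert (owners_of_pixels == owner).all()

    def test_merged_puncta_become_one_focus_with_summed_intensity(self):
        """Two generator puncta fused at one location segment as one focus
        whose integrated intensity approximates the pair's sum."""
        from chromoquant import integrated_intensity

        nuclei = self._nucleus_map()
        # one blob carrying the mass of two puncta of 100 and 300
        total = 400.0
        sigma = 1.5
        amp = total / (2 * np.pi * sigma**2)
        mark = _gaussian_disk((40, 40), (20, 20), sigma, amp) + 1.0
        # manual threshold just above background, as set per image by eye
        foci = segment_foci(mark, nuclei, FociParams(focus_threshold=2.0))
        assert foci.n_objects == 1
        measured = integrated_intensity(foci.labels == 1, mark)
        background = (foci.labels == 1).sum() * 1.0
        assert measured - background == pytest.approx(total, rel=0.10)

    def test_shape_mismatch_rejected(self):
        nuclei = self._nucleus_map()
        with pytest.raises(ValueError, match="shape"):
            segment_foci(np.zeros((10, 10)), nuclei, FociParams())


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(smooth_radius_px=0), dict(h=0.0), dict(min_nucleus_area_px=0)],
    )
    def test_bad_segmentation_params(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs", [dict(focus_h=-1.0), dict(min_focus_area_px=0)]
    )
    def test_bad_foci_params(self, kwargs):
        with pytest.raises(ValueError):
            FociParams(**kwargs)
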