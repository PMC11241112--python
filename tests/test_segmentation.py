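import numpy as np
import pytest

from adcstab.pipeline import segmentation_image
from adcstab.segmentation import (
    RESIZE_LABELS,
    VARIANT_LABELS,
    SegmentationError,
    SegmentationMask,
    dice,
    make_variant_set,
    otsu_threshold,
    resize_variants,
    segment,
    shift_variants,
)
from adcstab.synthetic import PhantomConfig, generate_phantom

from .oracles import otsu_brute


class TestOtsu:
    def test_perfectly_bimodal_sample_splits_both_classes(self):
        values = np.array([0.0] * 50 + [100.0] * 50)
        t = otsu_threshold(values)
        assert 0.0 < t < 100.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_discriminant_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [rng.normal(40, 12, 120), rng.normal(160, 25, 80)]
        )
        assert otsu_threshold(values) == pytest.approx(otsu_brute(values))

    def test_shift_equivariance_within_one_bin(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 100), rng.normal(6, 1, 100)])
        bin_width = (values.max() - values.min()) / 256
        t0 = otsu_threshold(values)
        t1 = otsu_threshold(values + 17.5)
        assert abs((t1 - 17.5) - t0) <= bin_width + 1e-9

    def test_constant_sample_rejected(self):
        with pytest.raises(SegmentationError):
            otsu_threshold(np.full(20, 3.0))


class TestSegment:
    def test_threshold_below_all_values_returns_delineation(self):
        img = np.full((8, 8), 10.0)
        delin = np.zeros((8, 8), bool)
        delin[2:6, 2:6] = True
        mask = segment(img, delin, threshold=5.0)
        np.testing.assert_array_equal(mask.mask, delin)

    def test_pixel_equal_to_threshold_is_excluded(self):
        img = np.array([[5.0, 6.0], [7.0, 5.0]])
        delin = np.ones((2, 2), bool)
        mask = segment(img, delin, threshold=5.0)
        np.testing.assert_array_equal(mask.mask, [[False, True], [True, False]])

    def test_threshold_above_max_raises(self):
        with pytest.raises(SegmentationError):
            segment(np.ones((4, 4)), np.ones((4, 4), bool), threshold=2.0)

    def test_idempotent_for_fixed_threshold(self):
        rng = np.random.default_rng(0)
        img = rng.random((10, 10))
        delin = np.ones((10, 10), bool)
        m1 = segment(img, delin, 0.5)
        m2 = segment(img, m1.mask, 0.5)
        np.testing.assert_array_equal(m1.mask, m2.mask)


class TestResize:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_masks_nest_monotonically(self, seed):
        case = generate_phantom(PhantomConfig(seed=seed))
        vs = make_variant_set(segmentation_image(case), case.delineation)
        for lower, higher in zip(RESIZE_LABELS_SORTED[:-1], RESIZE_LABELS_SORTED[1:]):
            low, high = vs[lower].mask, vs[higher].mask
            assert (low | high == low).all(), f"{higher} not nested in {lower}"

    def test_factor_one_is_identity(self, phantom_case):
        img = segmentation_image(phantom_case)
        t = otsu_threshold(img[phantom_case.delineation])
        original = segment(img, phantom_case.delineation, t)
        (same,) = resize_variants(img, phantom_case.delineation, t, factors=(1.0,))
        np.testing.assert_array_equal(original.mask, same.mask)

    def test_default_factors_yield_four_masks(self, phantom_case):
        img = segmentation_image(phantom_case)
        t = otsu_threshold(img[phantom_case.delineation])
        masks = resize_variants(img, phantom_case.delineation, t)
        assert [m.variant_label for m in masks] == ["th80", "th90", "th110", "th120"]


RESIZE_LABELS_SORTED = ("th80", "th90", "original", "th110", "th120")


class TestShift:
    def test_single_pixel_lands_on_four_neighbors(self):
        m = np.zeros((21, 21), bool)
        m[10, 10] = True
        shifted = {s.variant_label: s.mask for s in shift_variants(
            SegmentationMask(m, "original", 0.0)
        )}
        assert shifted["shift+x"][10, 11]
        assert shifted["shift-x"][10, 9]
        assert shifted["shift+y"][11, 10]
        assert shifted["shift-y"][9, 10]

    def test_pixel_count_preserved_and_inverse_recovers(self, phantom_case):
        vs = make_variant_set(
            segmentation_image(phantom_case), phantom_case.delineation
        )
        original = vs["original"]
        for label in ("shift+x", "shift-x", "shift+y", "shift-y"):
            assert vs[label].size == original.size
        back = np.roll(vs["shift+x"].mask, -1, axis=1)
        np.testing.assert_array_equal(back, original.mask)

    def test_border_touching_mask_rejected(self):
        m = np.zeros((8, 8), bool)
        m[0, 3] = True
        with pytest.raises(SegmentationError):
            shift_variants(SegmentationMask(m, "original", 0.0))


class TestVariantSet:
    def test_nine_canonical_variants(self, phantom_case):
        vs = make_variant_set(
            segmentation_image(phantom_case), phantom_case.delineation, "c1"
        )
        assert set(vs.variants) == set(VARIANT_LABELS)
        assert len(vs.variants) == 9

    def test_homogeneous_region_propagates_otsu_error(self):
        img = np.full((16, 16), 5.0)
        delin = np.zeros((16, 16), bool)
        delin[4:10, 4:10] = True
        with pytest.raises(SegmentationError):
            make_variant_set(img, delin)

    def test_dice_of_resized_variant_in_unit_interval(self, phantom_case):
        vs = make_variant_set(
            segmentation_image(phantom_case), phantom_case.delineation
        )
        d = dice(vs["original"], vs["th90"])
        assert 0.0 < d <= 1.0
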