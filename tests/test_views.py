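"""Geometry, pixel provenance and view-batch contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clib.views import (AugmentationPolicy, CropGeometry, GeometryError,
                        ImageBatch, build_three_view_batch,
                        build_two_view_batch, extract_background,
                        extract_pair, extract_subject, resize_bilinear)

from conftest import checkerboard


def indexed_image(h, w):
    """Pixel value encodes its (row, col) so provenance is checkable."""
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy * w + xx) / (h * w))[..., None].repeat(3, axis=2)


class TestSubjectExtraction:
    def test_identity_at_alpha_one(self):
        img = indexed_image(64, 64)
        g = CropGeometry(alpha=1.0, beta=1.0)
        assert np.array_equal(extract_subject(img, g), img)

    @pytest.mark.parametrize("h,w,alpha,expect", [
        (64, 64, 0.5, (16, 48, 16, 48)),
        (224, 224, 0.5, (56, 168, 56, 168)),
        (33, 33, 0.5, (8, 24, 8, 24)),  # odd size: floor rounding
    ])
    def test_centered_crop_indices(self, h, w, alpha, expect):
        img = indexed_image(h, w)
        g = CropGeometry(alpha=alpha, beta=alpha)
        crop = extract_subject(img, g)
        r0, r1, c0, c1 = expect
        assert crop.shape[:2] == (r1 - r0, c1 - c0)
        assert np.array_equal(crop, img[r0:r1, c0:c1])

    def test_zero_size_crop_rejected(self):
        img = indexed_image(8, 8)
        with pytest.raises(GeometryError):
            extract_subject(img, CropGeometry(alpha=0.05, beta=0.05))


class TestBackgroundExtraction:
    def test_mosaic_quadrants_from_corners(self):
        img = indexed_image(64, 64)
        g = CropGeometry(gamma=0.25, delta=0.25)
        mosaic = extract_background(img, g)
        assert mosaic.shape[:2] == (32, 32)
        assert np.array_equal(mosaic[:16, :16], img[:16, :16])
        assert np.array_equal(mosaic[:16, 16:], img[:16, 48:])
        assert np.array_equal(mosaic[16:, :16], img[48:, :16])
        assert np.array_equal(mosaic[16:, 16:], img[48:, 48:])

    def test_half_ratio_mosaic_is_pixel_permutation(self):
        img = indexed_image(64, 64)
        mosaic = extract_background(img, CropGeometry(gamma=0.5, delta=0.5))
        assert mosaic.shape == img.shape
        assert np.array_equal(np.sort(mosaic.ravel()), np.sort(img.ravel()))

    def test_constant_image_gives_constant_mosaic(self):
        img = np.full((40, 40, 3), 0.37)
        mosaic = extract_background(img, CropGeometry())
        assert np.allclose(mosaic, 0.37)

    def test_corner_rounds_to_zero_rejected(self):
        with pytest.raises(GeometryError):
            extract_background(indexed_image(4, 4), CropGeometry(gamma=0.2, delta=0.2))


class TestExtractPair:
    def test_matches_individual_ops(self):
        img = indexed_image(48, 48)
        g = CropGeometry()
        sub, bac = extract_pair(img, g)
        assert np.array_equal(sub, extract_subject(img, g))
        assert np.array_equal(bac, extract_background(img, g))

    def test_subject_and_corners_disjoint(self):
        """With gamma <= (1-alpha)/2 the corner index sets never touch the
        subject rectangle; the center motif appears only in the subject."""
        img = checkerboard()
        g = CropGeometry(alpha=0.5, beta=0.5, gamma=0.25, delta=0.25)
        sub, bac = extract_pair(img, g)
        assert (sub == 0.5).any()
        assert not (bac == 0.5).any()

    @given(alpha=st.floats(0.2, 1.0), gamma=st.floats(0.05, 0.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_provenance_index_sets(self, alpha, gamma):
        """Every crop pixel maps to exactly one source pixel, and the subject
        and corner index sets are disjoint whenever gamma <= (1-alpha)/2."""
        h = w = 40
        img = indexed_image(h, w)
        g = CropGeometry(alpha=alpha, beta=alpha, gamma=gamma, delta=gamma)
        sub = extract_subject(img, g)
        bac = extract_background(img, g)
        values = img[..., 0].ravel()
        sub_ids = set(np.round(sub[..., 0].ravel() * h * w).astype(int))
        bac_ids = np.round(bac[..., 0].ravel() * h * w).astype(int)
        assert len(set(bac_ids)) == bac[..., 0].size  # no duplicated source pixel
        assert set(bac_ids) <= set(np.round(values * h * w).astype(int))
        if gamma <= (1 - alpha) / 2:
            assert sub_ids.isdisjoint(bac_ids)

    def test_corners_tile_image_at_half_ratio(self):
        img = indexed_image(64, 64)
        bac = extract_background(img, CropGeometry(gamma=0.5, delta=0.5))
        assert set(bac[..., 0].ravel()) == set(img[..., 0].ravel())


class TestBatchBuilders:
    @pytest.mark.parametrize("n", list(range(1, 9)))
    def test_three_view_counting(self, n, geometry, identity_policy):
        batch = ImageBatch(pixels=np.random.default_rng(n).random((n, 32, 32, 3)))
        vb = build_three_view_batch(batch, geometry, identity_policy, seed=0)
        assert len(vb.samples) == 3 * n
        assert vb.positive_pairs == [(i, i + n) for i in range(n)]
        assert vb.negatives_per_anchor == 3 * n - 2
        assert vb.n_anchors == 2 * n
        assert all(j < 2 * n for pair in vb.positive_pairs for j in pair)

    def test_identity_policy_preserves_originals(self, identity_policy):
        rng = np.random.default_rng(0)
        pixels = rng.random((4, 32, 32, 3))
        g = CropGeometry(alpha=1.0, beta=1.0, output_size=(32, 32))
        vb = build_three_view_batch(ImageBatch(pixels=pixels), g,
                                    identity_policy, seed=0)
        assert np.array_equal(vb.samples[:4], pixels)

    def test_same_seed_reproduces(self, geometry, tiny_batch):
        policy = AugmentationPolicy()
        a = build_three_view_batch(tiny_batch, geometry, policy, seed=42)
        b = build_three_view_batch(tiny_batch, geometry, policy, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = build_three_view_batch(tiny_batch, geometry, policy, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_two_view_counting(self, geometry, tiny_batch):
        policy = AugmentationPolicy()
        vb = build_two_view_batch(tiny_batch, policy, seed=0, geometry=geometry)
        assert len(vb.samples) == 16 and vb.layout == "two_view"
        assert vb.negatives_per_anchor == 2 * 8 - 2
        vbg = build_two_view_batch(tiny_batch, policy, seed=0,
                                   with_background=True, geometry=geometry)
        assert len(vbg.samples) == 24 and vbg.layout == "two_view_bg"
        assert vbg.n_anchors == 16
        assert vbg.negatives_per_anchor == 3 * 8 - 2

    def test_two_view_deterministic(self, geometry, tiny_batch):
        policy = AugmentationPolicy()
        a = build_two_view_batch(tiny_batch, policy, seed=5, geometry=geometry)
        b = build_two_view_batch(tiny_batch, policy, seed=5, geometry=geometry)
        assert np.array_equal(a.samples, b.samples)


class TestAugmentationAndResize:
    def test_resize_identity_when_same_shape(self):
        img = np.random.default_rng(0).random((32, 32, 3))
        assert np.array_equal(resize_bilinear(img, 32, 32), img)

    def test_resize_constant_preserved(self):
        img = np.full((20, 30, 3), 0.6)
        out = resize_bilinear(img, 32, 32)
        assert out.shape == (32, 32, 3)
        assert np.allclose(out, 0.6)

    def test_policy_output_shape_and_range(self, rng):
        policy = AugmentationPolicy()
        img = rng.random((48, 40, 3))
        out = policy.apply(img, (32, 32), rng)
        assert out.shape == (32, 32, 3)
        assert out.min() >= 0 and out.max() <= 1

    def test_policy_seed_determinism(self):
        policy = AugmentationPolicy()
        img = np.random.default_rng(3).random((32, 32, 3))
        a = policy.apply(img, (32, 32), np.random.default_rng(11))
        b = policy.apply(img, (32, 32), np.random.default_rng(11))
        assert np.array_equal(a, b)


class TestValidation:
    def test_rejects_out_of_range_pixels(self):
        with pytest.raises(ValueError):
            ImageBatch(pixels=np.full((2, 8, 8, 3), 1.5))

    def test_rejects_bad_ratios(self):
        with pytest.raises(GeometryError):
            CropGeometry(gamma=0.6, delta=0.6)
        with pytest.raises(GeometryError):
            CropGeometry(alpha=0.0, beta=0.0)
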