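"""HLAC sums, mean correction, max normalization, ACHLAC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from histotex.hlac import achlac, hlac, max_normalize, mean_correct
from histotex.masks import MaskSet, default_masks, enumerate_masks

PAIR_RIGHT = MaskSet((((0, 0), (0, 1)),), window_size=3, max_order=1)


def naive_hlac(img, masks):
    """Triple-loop reference: sum of products over the common interior."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    m = masks.margin
    out = np.zeros(len(masks))
    for k, mask in enumerate(masks):
        total = 0.0
        for r in range(m, h - m):
            for c in range(m, w - m):
                prod = 1.0
                for dr, dc in mask:
                    prod *= img[r + dr, c + dc]
                total += prod
        out[k] = total
    return out


class TestHlac:
    def test_neighbor_pair_products(self):
        """Adjacent pixels (2, 125) and (15, 16) contribute 250 and 240."""
        for pair, product in [((2, 125), 250.0), ((15, 16), 240.0)]:
            img = np.zeros((6, 6))
            img[2, 2], img[2, 3] = pair
            assert hlac(img, PAIR_RIGHT)[0] == product

    def test_all_ones_counts_interior_positions(self, masks25):
        feats = hlac(np.ones((4, 4)), masks25)
        assert np.array_equal(feats, np.full(25, 4.0))

    def test_zero_image_gives_zero_vector(self, masks25):
        assert not hlac(np.zeros((8, 8)), masks25).any()

    def test_matches_naive_reference(self, rng, masks25):
        for _ in range(5):
            img = rng.uniform(0, 255, (12, 9))
            np.testing.assert_allclose(
                hlac(img, masks25), naive_hlac(img, masks25), rtol=1e-12
            )

    def test_homogeneous_of_degree_cardinality(self, rng, masks25):
        img = rng.uniform(0, 10, (8, 8))
        base = hlac(img, masks25)
        scaled = hlac(1.7 * img, masks25)
        degrees = np.array([len(m) for m in masks25])
        np.testing.assert_allclose(scaled, base * 1.7**degrees, rtol=1e-10)

    def test_torus_mode_exactly_translation_invariant(self, rng, masks25):
        img = rng.uniform(0, 255, (10, 12))
        rolled = np.roll(img, (3, -4), axis=(0, 1))
        np.testing.assert_allclose(
            hlac(img, masks25, mode="wrap"),
            hlac(rolled, masks25, mode="wrap"),
            rtol=1e-12,
        )

    def test_per_position_normalization_flag(self, masks25):
        feats = hlac(np.ones((4, 4)), masks25, normalize=True)
        assert np.array_equal(feats, np.ones(25))

    def test_empty_mask_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hlac(np.ones((4, 4)), MaskSet((), 3, 0))

    def test_image_smaller_than_margin_rejected(self, masks25):
        with pytest.raises(ValueError, match="small"):
            hlac(np.ones((2, 2)), masks25)


class TestMeanCorrect:
    def test_constant_image_maps_to_zero(self):
        assert not mean_correct(np.full((4, 4), 9)).any()

    def test_two_pixel_image(self):
        np.testing.assert_array_equal(
            mean_correct(np.array([[0.0, 100.0]])), [[50.0, 50.0]]
        )

    def test_mean_equals_mean_absolute_deviation(self, rng):
        img = rng.integers(0, 256, (7, 9)).astype(float)
        corrected = mean_correct(img)
        assert corrected.mean() == pytest.approx(np.abs(img - img.mean()).mean())


class TestMaxNormalize:
    def test_divides_by_maximum(self):
        np.testing.assert_array_equal(max_normalize([2.0, 4.0]), [0.5, 1.0])

    def test_all_zero_stays_zero(self):
        assert not max_normalize(np.zeros(5)).any()

    def test_maximum_of_output_is_one(self, rng):
        v = max_normalize(rng.uniform(0.1, 9.0, 25))
        assert v.max() == 1.0 and v.min() >= 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            max_normalize([-1.0, 2.0])


class TestAchlac:
    def test_constant_image_gives_zero_vector(self, masks25):
        assert not achlac(np.full((8, 8), 120), masks25).any()

    def test_range_and_attained_maximum(self, rng, masks25):
        v = achlac(rng.integers(0, 256, (16, 16)), masks25)
        assert v.min() >= 0.0 and v.max() == 1.0

    @given(st.integers(0, 100))
    def test_invariant_to_constant_shift(self, shift):
        rng = np.random.default_rng(11)
        img = rng.integers(0, 150, (10, 10)).astype(float)
        masks = default_masks()
        np.testing.assert_allclose(
            achlac(img, masks), achlac(img + shift, masks), rtol=1e-12
        )

    def test_separates_pairs_with_equal_products(self, masks25):
        """The (2, 125) and (15, 16) neighborhoods multiply to nearly the
        same raw value (250 vs 240) but have very different local spread;
        ACHLAC tells them apart where raw HLAC barely does."""
        imgs = []
        for pair in [(2, 125), (15, 16)]:
            img = np.full((8, 8), 60.0)
            img[3, 3], img[3, 4] = pair
            imgs.append(img)
        raw = [hlac(i, PAIR_RIGHT)[0] for i in imgs]
        ach = [achlac(i, masks25) for i in imgs]
        raw_rel = abs(raw[0] - raw[1]) / max(raw)
        ach_gap = np.abs(ach[0] - ach[1]).max()
        assert raw_rel < 0.05
        assert ach_gap > 10 * raw_rel


def test_extended_masks_probe_wider_support(rng):
    """Scaled masks (radius 5) see structure at stride 2 that base masks miss."""
    from histotex.masks import scale_masks

    masks5 = scale_masks(default_masks(), 5)
    img = rng.uniform(0, 255, (14, 14))
    base = hlac(img, default_masks())
    ext = hlac(img, masks5)
    assert ext.shape == base.shape
    assert not np.allclose(base, ext)
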