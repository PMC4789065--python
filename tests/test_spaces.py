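"""Analysis-space mapping: gray conversion, entropy, LBP, channel selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from histotex.spaces import (
    channel_extract,
    entropy_map,
    lbp_map,
    map_spaces,
    shannon_entropy,
    to_gray,
)


def rgb_const(r, g, b, shape=(5, 5)):
    img = np.zeros(shape + (3,), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img


class TestToGray:
    def test_achromatic_input_is_identity(self):
        assert np.array_equal(to_gray(rgb_const(77, 77, 77)), np.full((5, 5), 77))

    def test_all_black(self):
        assert not to_gray(rgb_const(0, 0, 0)).any()

    def test_pure_red_luma(self):
        # 0.299 * 255 = 76.245 -> 76 after round-half-up
        assert to_gray(rgb_const(255, 0, 0))[0, 0] == 76


class TestChannelExtract:
    def test_named_channels(self):
        img = rgb_const(10, 20, 30)
        assert channel_extract(img, "R")[0, 0] == 10
        assert channel_extract(img, "B")[0, 0] == 30

    def test_round_trip(self, rng):
        img = rng.integers(0, 256, (6, 7, 3), dtype=np.uint8)
        rebuilt = np.stack([channel_extract(img, ch) for ch in "RGB"], axis=-1)
        assert np.array_equal(rebuilt, img)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            channel_extract(rgb_const(1, 2, 3), "X")


class TestShannonEntropy:
    def test_degenerate_distribution(self):
        h = np.zeros(256)
        h[17] = 1.0
        assert shannon_entropy(h) == 0.0

    def test_uniform_is_eight_bits(self):
        assert shannon_entropy(np.full(256, 1 / 256)) == pytest.approx(8.0)

    def test_two_levels_one_bit(self):
        h = np.zeros(256)
        h[[0, 255]] = 0.5
        assert shannon_entropy(h) == pytest.approx(1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            shannon_entropy(np.full(256, 0.5))


class TestEntropyMap:
    def test_constant_image_maps_to_zero(self):
        assert not entropy_map(np.full((12, 12), 90), window=9).any()

    def test_checkerboard_interior_is_one_bit(self):
        board = np.indices((15, 15)).sum(axis=0) % 2 * 255
        ent = entropy_map(board, window=9)
        # 41/40 split over two levels: H = 0.9999 bits -> 32 on the 8-bit scale
        assert ent[7, 7] == 32

    def test_output_range_and_shape(self, rng):
        img = rng.integers(0, 256, (20, 24))
        ent = entropy_map(img, window=5)
        assert ent.shape == img.shape
        assert ent.dtype == np.uint8

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            entropy_map(np.zeros((5, 5)), window=9)

    def test_invariant_to_constant_shift(self, rng):
        img = rng.integers(0, 200, (16, 16))
        assert np.array_equal(entropy_map(img, 5), entropy_map(img + 55, 5))


class TestLbpMap:
    def test_constant_image_is_zero(self):
        assert not lbp_map(np.full((6, 6), 50)).any()

    def test_all_brighter_neighbors_give_255(self):
        img = np.full((3, 3), 10)
        img[1, 1] = 5
        assert lbp_map(img)[1, 1] == 255

    @pytest.mark.parametrize(
        "neighbor, bit",
        [((0, 0), 128), ((0, 1), 64), ((0, 2), 32), ((1, 2), 16),
         ((2, 2), 8), ((2, 1), 4), ((2, 0), 2), ((1, 0), 1)],
    )
    def test_bit_order_top_left_clockwise_msb_first(self, neighbor, bit):
        img = np.full((3, 3), 5)
        img[neighbor] = 10
        assert lbp_map(img)[1, 1] == bit

    def test_invariant_to_constant_shift(self, rng):
        img = rng.integers(0, 200, (10, 10))
        assert np.array_equal(lbp_map(img), lbp_map(img + 55))

    def test_mirroring_permutes_bits(self, rng):
        img = rng.integers(0, 256, (9, 11))
        mirrored = lbp_map(img[:, ::-1])[:, ::-1]
        code = lbp_map(img)
        # horizontal mirror swaps bit pairs (7,5), (4,0), (3,1); 6 and 2 fixed
        expected = (
            ((code >> 7) & 1) << 5 | ((code >> 5) & 1) << 7
            | ((code >> 4) & 1) << 0 | ((code >> 0) & 1) << 4
            | ((code >> 3) & 1) << 1 | ((code >> 1) & 1) << 3
            | (code & 0b01000100)
        )
        assert np.array_equal(mirrored, expected.astype(np.uint8))


@given(st.integers(0, 150))
def test_maps_depend_only_on_relative_structure(shift):
    rng = np.random.default_rng(3)
    img = rng.integers(0, 100, (12, 12))
    assert np.array_equal(lbp_map(img), lbp_map(img + shift))
    assert np.array_equal(entropy_map(img, 5), entropy_map(img + shift, 5))


def test_map_spaces_returns_all_four(rng):
    img = rng.integers(0, 256, (16, 20, 3), dtype=np.uint8)
    maps = map_spaces(img)
    assert set(maps) == {"entropy", "lbp", "R", "B"}
    for m in maps.values():
        assert m.shape == (16, 20)
    assert np.array_equal(maps["R"], img[..., 0])
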