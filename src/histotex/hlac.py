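"""HLAC, extended-HLAC and average-correction HLAC (ACHLAC) features.

The HLAC feature for a mask ``{(0,0), a_1, ..., a_N}`` is

    x = sum_r f(r) * f(r + a_1) * ... * f(r + a_N)

over all positions ``r`` where every offset lands inside the image.  Raw
HLAC products conflate very different local distributions: the pixel pairs
(2, 125) and (15, 16) multiply to 250 and 240 even though the first pair has
far higher local spread.  ACHLAC addresses this by first replacing every
pixel with its absolute deviation from the image's global mean gray value,
computing HLAC on that corrected raster, and max-normalizing the resulting
vector to [0, 1] so image size does not change the scale.
"""

from __future__ import annotations

import numpy as np

from .masks import MaskSet


def mean_correct(img: np.ndarray) -> np.ndarray:
    """Absolute deviation of each pixel from the global mean gray value.

    The result is kept in floating precision: re-quantizing would destroy
    the small deviations ACHLAC is designed to amplify.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image is empty")
    return np.abs(img - img.mean())


def hlac(
    img: np.ndarray,
    masks: MaskSet,
    mode: str = "valid",
    normalize: bool = False,
) -> np.ndarray:
    """HLAC feature vector of ``img`` under a mask set.

    Parameters
    ----------
    img : 2-D array
        Gray raster (any non-negative dtype; computed in float64).
    masks : MaskSet
        Templates to evaluate, one feature per mask, in mask order.
    mode : {'valid', 'wrap'}
        'valid' sums over the common interior where every offset of the
        *largest* mask extent stays in bounds, so all features are sums over
        the same positions and remain commensurable.  'wrap' treats the
        image as a torus (cyclic indexing), making the features exactly
        translation invariant; mainly useful for testing the shift-invariance
        contract.
    normalize : bool
        If True, divide each feature by the number of summed positions.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("img must be 2-D")
    if len(masks) == 0:
        raise ValueError("mask set is empty")
    h, w = img.shape
    m = masks.margin
    if mode == "valid":
        if h <= 2 * m or w <= 2 * m:
            raise ValueError(
                f"image {h}x{w} too small for masks with margin {m}"
            )
        n_pos = (h - 2 * m) * (w - 2 * m)
        feats = np.empty(len(masks))
        for i, mask in enumerate(masks):
            prod = np.ones((h - 2 * m, w - 2 * m))
            for dr, dc in mask:
                prod *= img[m + dr : h - m + dr, m + dc : w - m + dc]
            feats[i] = prod.sum()
    elif mode == "wrap":
        n_pos = h * w
        feats = np.empty(len(masks))
        for i, mask in enumerate(masks):
            prod = np.ones((h, w))
            for dr, dc in mask:
                prod *= np.roll(img, (-dr, -dc), axis=(0, 1))
            feats[i] = prod.sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if normalize:
        feats /= n_pos
    return feats


def max_normalize(v: np.ndarray) -> np.ndarray:
    """Divide a feature vector by its maximum element, mapping it into [0, 1].

    An all-zero vector is returned unchanged (degenerate rule).  Negative
    elements are rejected: HLAC sums of non-negative rasters are non-negative.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size and v.min() < 0:
        raise ValueError("max_normalize expects non-negative features")
    top = v.max(initial=0.0)
    if top == 0.0:
        return v.copy()
    return v / top


def achlac(img: np.ndarray, masks: MaskSet, mode: str = "valid") -> np.ndarray:
    """Average-correction HLAC: mean-correct, HLAC, then max-normalize.

    Equals ``max_normalize(hlac(mean_correct(img), masks))``; 25 values under
    the default mask set.  Adding a constant to every pixel leaves the result
    unchanged, and a constant image yields the zero vector.
    """
    return max_normalize(hlac(mean_correct(img), masks, mode=mode))
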