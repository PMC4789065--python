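"""Multispatial mapping of an RGB histopathology image.

HE staining renders nuclei purple-blue and cytoplasm pink-red, so the R and
B channels of a stained section carry most of the stain contrast, while a
local-entropy map and a local-binary-pattern (LBP) map expose texture.  The
four analysis spaces used throughout the package are therefore
``entropy``, ``lbp``, ``R`` and ``B``; each is an 8-bit gray raster with the
same height and width as the input.
"""

from __future__ import annotations

import numpy as np
from skimage.filters.rank import entropy as _rank_entropy

#: ITU-R 601 luma weights used for gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Canonical space names, in pipeline order.
SPACE_NAMES = ("entropy", "lbp", "R", "B")

# LBP neighbor order: start at the top-left neighbor and proceed clockwise;
# the first neighbor takes the most significant bit.
_LBP_NEIGHBORS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3 x 3")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return img


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray array, got shape {img.shape}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return img


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma-weighted gray conversion (ITU-R 601), rounded half-up to uint8."""
    img = _as_rgb(img)
    luma = (
        LUMA_WEIGHTS[0] * img[..., 0].astype(np.float64)
        + LUMA_WEIGHTS[1] * img[..., 1]
        + LUMA_WEIGHTS[2] * img[..., 2]
    )
    return np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)


def channel_extract(img: np.ndarray, channel: str) -> np.ndarray:
    """Return the named color channel ('R', 'G' or 'B') unchanged."""
    img = _as_rgb(img)
    try:
        idx = "RGB".index(channel)
    except ValueError:
        raise ValueError(f"unknown channel {channel!r}; expected 'R', 'G' or 'B'") from None
    return np.ascontiguousarray(img[..., idx])


def shannon_entropy(hist: np.ndarray) -> float:
    """Shannon entropy in bits of a 256-bin gray-level histogram.

    ``hist`` must be a probability vector (non-negative, summing to 1).  The
    convention ``0 * log 0 = 0`` applies; the result lies in ``[0, 8]`` bits.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("histogram must have 256 bins")
    if hist.min() < 0 or abs(hist.sum() - 1.0) > 1e-8:
        raise ValueError("histogram must be a probability vector summing to 1")
    p = hist[hist > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_map(img: np.ndarray, window: int = 9) -> np.ndarray:
    """Sliding-window local-entropy map, rescaled to 8 bits.

    For each pixel the Shannon entropy (bits) of the gray-level histogram in
    the centered ``window x window`` neighborhood is computed and linearly
    rescaled from ``[0, 8]`` bits to ``[0, 255]``.  Borders are handled by
    edge replication so the output has the input's shape.
    """
    img = _as_gray(img)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(img.shape):
        raise ValueError("window larger than image")
    half = window // 2
    padded = np.pad(np.round(img).astype(np.uint8), half, mode="edge")
    ent = _rank_entropy(padded, np.ones((window, window), dtype=bool))
    ent = ent[half:-half, half:-half]
    return np.floor(ent * (255.0 / 8.0) + 0.5).clip(0, 255).astype(np.uint8)


def lbp_map(img: np.ndarray) -> np.ndarray:
    """Local-binary-pattern map over the 3 x 3 neighborhood.

    Each of the 8 neighbors is compared to the central pixel with a strict
    "greater than": a neighbor strictly brighter than the center contributes
    a 1 bit, ties and darker neighbors a 0 bit.  Bits are assembled starting
    at the top-left neighbor, clockwise, most significant bit first, giving a
    code in ``[0, 255]``.  Borders are edge-replicated.
    """
    img = _as_gray(img)
    padded = np.pad(img, 1, mode="edge")
    h, w = img.shape
    center = padded[1 : 1 + h, 1 : 1 + w]
    code = np.zeros((h, w), dtype=np.uint8)
    for bit, (dr, dc) in enumerate(_LBP_NEIGHBORS):
        neighbor = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        code |= (neighbor > center).astype(np.uint8) << (7 - bit)
    return code


def map_spaces(
    img: np.ndarray,
    spaces: tuple[str, ...] = SPACE_NAMES,
    entropy_window: int = 9,
) -> dict[str, np.ndarray]:
    """Map an RGB image into the requested analysis spaces.

    Returns a dict keyed by space name ('entropy', 'lbp', 'R', 'B'), each an
    8-bit gray raster of the input's height and width.
    """
    img = _as_rgb(img)
    gray = None
    out: dict[str, np.ndarray] = {}
    for name in spaces:
        if name in ("entropy", "lbp") and gray is None:
            gray = to_gray(img)
        if name == "entropy":
            out[name] = entropy_map(gray, window=entropy_window)
        elif name == "lbp":
            out[name] = lbp_map(gray)
        elif name in ("R", "B", "G"):
            out[name] = channel_extract(img, name)
        else:
            raise ValueError(f"unknown space {name!r}")
    return out
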