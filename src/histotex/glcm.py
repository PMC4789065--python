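"""Gray-level co-occurrence (Haralick) features: 4 directions x 4 statistics.

Directions follow the (row, col) = (d sin θ, d cos θ) convention of
scikit-image's ``graycomatrix``: θ = 0° pairs each pixel with its right
neighbor (0, d), 45° with the lower-right diagonal (d, d), 90° with the
pixel below (d, 0), and 135° with the lower-left diagonal (d, -d).
Matrices are accumulated symmetrically (each pair counted in both orders)
and normalized to a joint probability distribution before statistics are
taken.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

#: Directions (degrees) in feature-vector order.
THETAS = (0, 45, 90, 135)

#: Statistic names in feature-vector order.
STAT_NAMES = ("energy", "contrast", "correlation", "homogeneity")


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize an 8-bit gray raster into ``levels`` bins."""
    img = np.asarray(img)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return np.minimum((img.astype(np.float64) * levels / 256).astype(np.intp), levels - 1)


def glcm(img: np.ndarray, theta: float, distance: int = 1, levels: int = 16) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction.

    Parameters
    ----------
    theta : degrees, one of 0, 45, 90, 135
    distance : pixel displacement along the direction
    levels : number of uniform gray quantization bins
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("img must be 2-D")
    if distance < 1 or distance >= max(img.shape):
        raise ValueError("distance must be >= 1 and smaller than the image extent")
    if theta not in THETAS:
        raise ValueError(f"theta must be one of {THETAS}")
    quant = quantize(img, levels).astype(np.uint8)
    mat = graycomatrix(
        quant,
        distances=[distance],
        angles=[np.deg2rad(theta)],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    return mat[:, :, 0, 0]


def glcm_stats(mat: np.ndarray) -> np.ndarray:
    """Energy, contrast, correlation and homogeneity of a normalized GLCM.

    energy      = sum p^2
    contrast    = sum (i - j)^2 p
    correlation = sum (i - mu_i)(j - mu_j) p / (sigma_i sigma_j), defined as
                  1 when either marginal variance vanishes (a constant image
                  is perfectly self-similar)
    homogeneity = sum p / (1 + |i - j|)
    """
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if mat.min() < 0 or abs(mat.sum() - 1.0) > 1e-8:
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    n = mat.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    energy = float((mat**2).sum())
    contrast = float(((i - j) ** 2 * mat).sum())
    homogeneity = float((mat / (1.0 + np.abs(i - j))).sum())
    mu_i = float((i * mat).sum())
    mu_j = float((j * mat).sum())
    var_i = float(((i - mu_i) ** 2 * mat).sum())
    var_j = float(((j - mu_j) ** 2 * mat).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * mat).sum()) / np.sqrt(var_i * var_j)
        )
    return np.array([energy, contrast, correlation, homogeneity])


def glcm_feature_vector(img: np.ndarray, distance: int = 1, levels: int = 16) -> np.ndarray:
    """The 16 co-occurrence features: 4 statistics at each of the 4 directions.

    Order: θ ascending (0°, 45°, 90°, 135°); within a direction energy,
    contrast, correlation, homogeneity.
    """
    return np.concatenate(
        [glcm_stats(glcm(img, th, distance=distance, levels=levels)) for th in THETAS]
    )


def glcm_feature_names() -> list[str]:
    """Column names matching :func:`glcm_feature_vector`'s order."""
    return [f"d{th:03d}_{stat}" for th in THETAS for stat in STAT_NAMES]
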