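"""Seeded two-class generator of HE-like texture images.

Real HE-stained liver sections are not redistributable, so tests and
examples run on synthetic stand-ins that copy the statistical structure the
method exploits: a pink-red cytoplasm background (eosin) scattered with
purple-blue elliptical nuclei (hematoxylin).  The abnormal class is drawn
with denser, larger and more irregular nuclei, giving it a strictly higher
local gray-value variance, while a global brightness correction matches the
two classes' mean gray level at batch level.  On top of that, every image
receives class-independent stain-intensity (brightness) and texture-gain
jitter, emulating the scan-to-scan staining variability of real slides.
With class means matched and per-image levels jittered, raw pixel-product
features carry little reliable class signal and the discrimination lives in
the local spread — the regime the average-correction HLAC feature (which is
invariant to per-image level and scale) is built for.

Every image is deterministic in (seed, label, index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .pipeline import NEGATIVE, POSITIVE


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic HE-texture generator.

    The defaults are the study conditions used throughout the test-suite:
    160 x 120 images, 50 per class, nuclei occupying a few percent of the
    normal-class area and an abnormal class with twice the nucleus load.
    """

    height: int = 120
    width: int = 160
    n_per_class: int = 50
    seed: int = 0
    #: Gaussian smoothing scale (px) of the cytoplasm background mottle.
    background_sigma: float = 6.0
    #: Std (gray levels) of the unsmoothed background mottle.
    background_amplitude: float = 20.0
    #: Std (gray levels) of fine per-pixel noise (keeps images non-constant).
    pixel_noise: float = 2.0
    #: Expected nucleus count per normal image.
    nucleus_density: float = 12.0
    #: Nucleus semi-axis range (px) for the normal class.
    radius_range: tuple[float, float] = (2.0, 4.0)
    #: Multiplier (> 1) on nucleus count/size for the abnormal class.
    abnormal_variance_multiplier: float = 2.0
    #: Stain hues: eosin pink cytoplasm, hematoxylin purple-blue nuclei.
    cytoplasm_rgb: tuple[int, int, int] = (232, 158, 186)
    nucleus_rgb: tuple[int, int, int] = (94, 58, 142)
    #: Target mean gray level both classes are corrected to.
    target_mean: float = 170.0
    #: Half-range (gray levels) of the class-independent per-image
    #: stain-intensity (brightness) jitter; emulates scan/stain variability.
    brightness_jitter: float = 12.0
    #: Relative half-range of the per-image background-mottle gain jitter.
    amplitude_jitter: float = 0.5

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValueError("image size too small to carry texture")
        if self.abnormal_variance_multiplier <= 1:
            raise ValueError("abnormal_variance_multiplier must exceed 1")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.radius_range) <= 0 or self.nucleus_density <= 0:
            raise ValueError("nucleus density and radii must be positive")


@dataclass
class LabeledDataset:
    """Images with class labels ('normal' negative / 'abnormal' positive)."""

    images: list[np.ndarray]
    labels: list[str]

    def __len__(self) -> int:
        return len(self.images)


def _draw_nuclei(canvas_alpha: np.ndarray, rng, count, r_lo, r_hi, irregularity):
    h, w = canvas_alpha.shape
    for _ in range(count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(r_lo, r_hi)
        ecc = rng.uniform(1.0 - 0.5 * irregularity, 1.0)
        b = a * ecc
        phi = rng.uniform(0, np.pi)
        ext = int(np.ceil(a)) + 2
        y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        d2 = (u / a) ** 2 + (v / b) ** 2
        alpha = np.clip(1.5 * (1.0 - d2), 0.0, 1.0)  # soft (anti-aliased) rim
        patch = canvas_alpha[y0:y1, x0:x1]
        np.maximum(patch, alpha * rng.uniform(0.75, 1.0), out=patch)


def generate_image(params: GeneratorParams, label: str, index: int = 0) -> np.ndarray:
    """One synthetic HE-like RGB image (uint8), deterministic per inputs."""
    if label not in (NEGATIVE, POSITIVE):
        raise ValueError(f"label must be {NEGATIVE!r} or {POSITIVE!r}")
    rng = np.random.default_rng([params.seed, int(label == POSITIVE), int(index)])
    h, w = params.height, params.width

    gain = rng.uniform(1.0 - params.amplitude_jitter, 1.0 + params.amplitude_jitter)
    mottle = gaussian_filter(
        rng.normal(0.0, gain * params.background_amplitude, (h, w)),
        params.background_sigma,
    )
    alpha = np.zeros((h, w))
    if label == POSITIVE:
        mult = params.abnormal_variance_multiplier
        count = int(round(params.nucleus_density * mult))
        r_lo, r_hi = (r * np.sqrt(mult) for r in params.radius_range)
        irregularity = 0.8
    else:
        count = int(round(params.nucleus_density))
        r_lo, r_hi = params.radius_range
        irregularity = 0.2
    _draw_nuclei(alpha, rng, count, r_lo, r_hi, irregularity)

    img = np.empty((h, w, 3))
    for ch in range(3):
        bg = params.cytoplasm_rgb[ch] + mottle
        img[..., ch] = bg * (1.0 - alpha) + params.nucleus_rgb[ch] * alpha
    img += rng.normal(0.0, params.pixel_noise, img.shape)

    # brightness correction: per-image mean gray is set to the shared target
    # plus a class-independent stain-intensity jitter, so the two classes are
    # matched in mean at batch level while individual images vary in level
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    level = params.target_mean + rng.uniform(
        -params.brightness_jitter, params.brightness_jitter
    )
    img += level - gray.mean()
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_dataset(params: GeneratorParams = GeneratorParams()) -> LabeledDataset:
    """Balanced labeled dataset: n_per_class normal + n_per_class abnormal."""
    images, labels = [], []
    for label in (NEGATIVE, POSITIVE):
        for i in range(params.n_per_class):
            images.append(generate_image(params, label, i))
            labels.append(label)
    return LabeledDataset(images, labels)


def save_dataset(dataset: LabeledDataset, out_dir: str | Path, params: GeneratorParams | None = None) -> Path:
    """Write class-named folders of PNGs plus a manifest CSV; returns the manifest path."""
    from PIL import Image

    out_dir = Path(out_dir)
    rows = []
    counters: dict[str, int] = {}
    for img, label in zip(dataset.images, dataset.labels):
        i = counters.get(label, 0)
        counters[label] = i + 1
        sub = out_dir / label
        sub.mkdir(parents=True, exist_ok=True)
        path = sub / f"{label}_{i:04d}.png"
        Image.fromarray(img).save(path)
        rows.append((str(path.relative_to(out_dir)), label))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("path,label\n")
        for path, label in rows:
            fh.write(f"{path},{label}\n")
    if params is not None:
        import dataclasses
        import json

        (out_dir / "params.json").write_text(
            json.dumps(dataclasses.asdict(params), indent=1)
        )
    return manifest
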