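"""Image and feature-table input/output helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG into an HxWx3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_gray_png(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit gray raster (e.g. a space map) as PNG."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_dataset_dir(root: str | Path) -> tuple[list[np.ndarray], list[str]]:
    """Read a class-folders-of-PNGs layout via its ``manifest.csv``."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    images = [load_image(root / p) for p in manifest["path"]]
    return images, list(manifest["label"])


def save_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="sample")


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")
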