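"""Image reading/writing helpers.

RGB inputs are 8-bit TIFF or PNG; stain concentration images are written
as 32-bit float TIFF; label masks as 16-bit TIFF/PNG; semantic maps as
8-bit indexed PNG using the documented palette (0 indeterminate,
1 background, 2 cytoplasm, 3 nucleus, 4 nucleus border).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "read_rgb",
    "write_rgb",
    "read_stain",
    "write_stain",
    "read_labels",
    "write_labels",
    "read_semantic",
    "write_semantic",
]


def read_rgb(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {img.shape}")
    return np.asarray(img, dtype=np.uint8)


def write_rgb(path, img: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def read_stain(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float32)


def write_stain(path, stain: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(stain, dtype=np.float32))


def read_labels(path) -> np.ndarray:
    arr = iio.imread(path) if str(path).endswith(".png") else tifffile.imread(path)
    return np.asarray(arr).astype(np.int32)


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit")
    out = labels.astype(np.uint16)
    if str(path).endswith(".png"):
        iio.imwrite(Path(path), out)
    else:
        tifffile.imwrite(Path(path), out)


def read_semantic(path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.max() > 4:
        raise ValueError(f"{path}: not a palette-coded semantic map")
    return arr.astype(np.uint8)


def write_semantic(path, semantic: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(semantic, dtype=np.uint8))
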