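"""Semantic nuclei-mask generation.

Three interchangeable back-ends produce the binary nuclei mask:

* ``cnn`` — per-pixel 4-class patch classification (the reference method);
* ``otsu`` — global Otsu threshold on the hematoxylin image;
* ``adaptive`` — per-pixel local-mean threshold.

Semantic maps use the palette of :mod:`nucseg.synth`: 0 indeterminate,
1 background, 2 cytoplasm, 3 nucleus, 4 nucleus border. Indeterminate is
only legal in reference maps; predictions label every pixel.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage import transform as sktransform
from skimage.filters import threshold_local, threshold_otsu

from .network import (
    CLASS_NAMES,
    ClassifierConfig,
    PatchClassifier,
    TrainingHistory,
    train_classifier,
)

__all__ = [
    "CLASS_NAMES",
    "ClassifierConfig",
    "PatchClassifier",
    "TrainingHistory",
    "train_classifier",
    "extract_patches",
    "augment",
    "predict_semantic_map",
    "mask_from_semantic",
    "mask_otsu",
    "mask_adaptive",
    "semantic_to_class",
    "class_to_semantic",
]

# palette value <-> class index (fixed class order of the classifier)
_PALETTE_TO_CLASS = {3: 0, 4: 1, 2: 2, 1: 3}  # nucleus, border, cytoplasm, background
_CLASS_TO_PALETTE = np.array([3, 4, 2, 1], dtype=np.uint8)


def semantic_to_class(semantic: np.ndarray) -> np.ndarray:
    """Palette-coded semantic map -> class indices; indeterminate -> -1."""
    out = np.full(semantic.shape, -1, dtype=np.int8)
    for pal, cls in _PALETTE_TO_CLASS.items():
        out[semantic == pal] = cls
    return out


def class_to_semantic(classes: np.ndarray) -> np.ndarray:
    """Class indices -> palette-coded semantic map."""
    return _CLASS_TO_PALETTE[np.asarray(classes)]


def extract_patches(
    stain: np.ndarray,
    reference: np.ndarray | None = None,
    size: int = 43,
    positions: np.ndarray | None = None,
):
    """Extract centered patches from a stain image.

    One patch per pixel whose reference label is not indeterminate (or per
    requested position). The image border is handled by reflection padding.

    Returns ``(patches, labels, positions)``; labels are class indices, or
    -1 everywhere when no reference is given.
    """
    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    stain = np.asarray(stain, dtype=np.float32)
    if stain.ndim != 2:
        raise ValueError("stain image must be 2-D")
    if reference is not None and reference.shape != stain.shape:
        raise ValueError("reference map must align with the stain image")
    half = size // 2
    padded = np.pad(stain, half, mode="reflect")
    windows = sliding_window_view(padded, (size, size))
    if positions is None:
        if reference is not None:
            classes = semantic_to_class(reference)
            ys, xs = np.nonzero(classes >= 0)
        else:
            ys, xs = np.meshgrid(
                np.arange(stain.shape[0]), np.arange(stain.shape[1]), indexing="ij"
            )
            ys, xs = ys.ravel(), xs.ravel()
        positions = np.stack([ys, xs], axis=1)
    else:
        positions = np.asarray(positions)
        ys, xs = positions[:, 0], positions[:, 1]
    patches = windows[ys, xs].astype(np.float32)
    if reference is not None:
        labels = semantic_to_class(reference)[ys, xs].astype(np.int64)
    else:
        labels = np.full(len(ys), -1, dtype=np.int64)
    return patches, labels, positions


def _random_transform(patch: np.ndarray, rng: np.random.Generator,
                      scale: tuple[float, float]) -> np.ndarray:
    """Random scale/rotate/flip of one patch, output shape preserved."""
    size = patch.shape[0]
    out = sktransform.rotate(
        patch.astype(float), rng.uniform(0.0, 360.0), mode="reflect", order=1
    )
    s = rng.uniform(*scale)
    out = sktransform.rescale(out, s, mode="reflect", order=1, anti_aliasing=False)
    if out.shape[0] >= size:  # center crop
        off = (out.shape[0] - size) // 2
        out = out[off : off + size, off : off + size]
    else:  # reflect-pad back up
        deficit = size - out.shape[0]
        lo = deficit // 2
        out = np.pad(out, (lo, deficit - lo), mode="reflect")
        out = out[:size, :size]
    if rng.random() < 0.5:
        out = out[::-1, :]
    if rng.random() < 0.5:
        out = out[:, ::-1]
    return out.astype(np.float32)


def augment(
    patches: np.ndarray,
    labels: np.ndarray,
    factor: int = 4,
    scale: tuple[float, float] = (0.8, 1.2),
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance the patch set by augmenting the nucleus-border class.

    Border patches (class 1) are multiplied ``factor`` times (originals plus
    ``factor - 1`` randomized scale/rotate/flip copies). Patches of every
    other class are randomly transformed in place, leaving class counts
    unchanged. Labels are never altered.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    patches = np.asarray(patches, dtype=np.float32)
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng_seed)
    border = labels == 1
    if factor > 1 and not border.any():
        warnings.warn("no nucleus-border patches to augment; returning input",
                      stacklevel=2)
        return patches.copy(), labels.copy()
    out_patches = [np.empty_like(patches)]
    out_labels = [labels.copy()]
    for i in range(len(patches)):
        if border[i] or factor == 1:
            out_patches[0][i] = patches[i]
        else:
            out_patches[0][i] = _random_transform(patches[i], rng, scale)
    for _ in range(factor - 1):
        extra = np.stack(
            [_random_transform(p, rng, scale) for p in patches[border]]
        ) if border.any() else np.empty((0,) + patches.shape[1:], dtype=np.float32)
        out_patches.append(extra)
        out_labels.append(labels[border].copy())
    return np.concatenate(out_patches), np.concatenate(out_labels)


def predict_semantic_map(
    model: PatchClassifier,
    stain: np.ndarray,
    batch_size: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every pixel of a stain image (stride-1 sliding window).

    Returns the palette-coded semantic map and the (H, W, 4) probability
    array. Argmax ties resolve to the first class in the fixed order
    (nucleus < nucleus_border < cytoplasm < background).
    """
    stain = np.asarray(stain, dtype=np.float32)
    if stain.ndim != 2:
        raise ValueError("stain image must be 2-D")
    size = model.config.patch_size
    h, w = stain.shape
    probs = np.empty((h * w, model.config.n_classes), dtype=np.float32)
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    positions = np.stack([ys.ravel(), xs.ravel()], axis=1)
    for start in range(0, len(positions), batch_size):
        chunk = positions[start : start + batch_size]
        patches, _, _ = extract_patches(stain, size=size, positions=chunk)
        probs[start : start + len(chunk)] = model.predict_proba(patches)
    classes = probs.argmax(axis=1).reshape(h, w)
    return class_to_semantic(classes), probs.reshape(h, w, model.config.n_classes)


def mask_from_semantic(semantic: np.ndarray, include_border: bool = False) -> np.ndarray:
    """Semantic map -> binary nuclei mask.

    Border pixels are excluded by default; this is what lets the CNN mask
    keep touching nuclei apart.
    """
    semantic = np.asarray(semantic)
    mask = semantic == 3  # nucleus palette value
    if include_border:
        mask |= semantic == 4
    return mask


def mask_otsu(stain: np.ndarray) -> np.ndarray:
    """Global Otsu threshold on the hematoxylin image (foreground above)."""
    stain = np.asarray(stain, dtype=float)
    if not np.all(np.isfinite(stain)):
        raise ValueError("stain image contains non-finite values")
    if np.ptp(stain) == 0:
        warnings.warn("constant image: Otsu threshold undefined, empty mask",
                      stacklevel=2)
        return np.zeros(stain.shape, dtype=bool)
    return stain > threshold_otsu(stain)


def mask_adaptive(stain: np.ndarray, window: int = 51,
                  offset: float = 0.0) -> np.ndarray:
    """Adaptive threshold: local mean over ``window``, minus ``offset``."""
    stain = np.asarray(stain, dtype=float)
    if not np.all(np.isfinite(stain)):
        raise ValueError("stain image contains non-finite values")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    thr = threshold_local(stain, block_size=window, method="mean", offset=offset)
    return stain > thr
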