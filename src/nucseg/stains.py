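"""Beer-Lambert optical density and supervised color deconvolution.

Converts 8-bit RGB microscopy images into per-stain concentration images
(hematoxylin, eosin, residual) using a fixed stain color matrix, and
provides the feature-wise (per-patch-position) standardization used to
prepare hematoxylin patches for classification.

Absorbance is base-10 throughout: ``OD = -log10(I / I0)``, so concentrations
are in conventional absorbance units and the forward model is
``I = I0 * 10**(-W @ C)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "PositionStats",
    "he_imagej_matrix",
    "rgb_to_optical_density",
    "deconvolve",
    "fit_position_stats",
    "standardize",
]

#: ImageJ colour-deconvolution H&E absorption vectors (RGB, unnormalized).
_IMAGEJ_HEMATOXYLIN = (0.650, 0.704, 0.286)
_IMAGEJ_EOSIN = (0.072, 0.990, 0.105)

STAIN_STD_FLOOR = 1e-6


@dataclass(frozen=True)
class StainMatrix:
    """3 x k matrix of unit-norm stain absorption vectors (columns)."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 3 or not 1 <= m.shape[1] <= 3:
            raise ValueError(f"stain matrix must be 3 x k (k<=3), got {m.shape}")
        if len(self.names) != m.shape[1]:
            raise ValueError("one name per stain column required")
        if np.any(m < 0):
            raise ValueError("stain vector entries must be non-negative")
        norms = np.linalg.norm(m, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("stain columns must have unit Euclidean norm")
        object.__setattr__(self, "matrix", m)

    @property
    def n_stains(self) -> int:
        return self.matrix.shape[1]


def he_imagej_matrix() -> StainMatrix:
    """Default H&E stain matrix: ImageJ vectors plus an orthogonal residual.

    Columns are hematoxylin, eosin and their normalized cross product
    (residual channel), each normalized to unit length.
    """
    h = np.array(_IMAGEJ_HEMATOXYLIN)
    e = np.array(_IMAGEJ_EOSIN)
    r = np.cross(h, e)
    r = np.abs(r)  # residual direction sign is arbitrary; keep entries >= 0
    cols = np.stack(
        [h / np.linalg.norm(h), e / np.linalg.norm(e), r / np.linalg.norm(r)], axis=1
    )
    return StainMatrix(cols, ("hematoxylin", "eosin", "residual"))


def load_stain_matrix_csv(path) -> StainMatrix:
    """Load a 3x3 stain matrix from CSV (rows = RGB, columns = stains)."""
    m = np.loadtxt(path, delimiter=",", dtype=float)
    m = np.atleast_2d(m)
    norms = np.linalg.norm(m, axis=0)
    norms[norms == 0] = 1.0
    k = m.shape[1]
    names = tuple(f"stain_{i}" for i in range(k))
    return StainMatrix(m / norms, names)


def rgb_to_optical_density(img: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Per-channel optical density ``-log10(max(I, 1) / i0)``.

    Parameters
    ----------
    img : (H, W, 3) array
        RGB intensities. Integer or float; values below 1 are clamped to 1
        so fully absorbed pixels stay finite.
    i0 : float
        Incident light intensity (8-bit white by default).
    """
    if not np.isscalar(i0) or i0 <= 0:
        raise ValueError(f"i0 must be a positive scalar, got {i0!r}")
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return -np.log10(np.maximum(img, 1.0) / float(i0))


def deconvolve(od: np.ndarray, w: StainMatrix | None = None) -> list[np.ndarray]:
    """Invert the stain mixing model: per pixel ``C = pinv(W) @ OD``.

    Returns one (H, W) concentration image per stain column, in matrix
    column order (hematoxylin, eosin, residual for the default matrix).
    """
    if w is None:
        w = he_imagej_matrix()
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) OD image, got shape {od.shape}")
    m = w.matrix
    rank = np.linalg.matrix_rank(m, tol=1e-8)
    if rank < m.shape[1]:
        # identify a collinear pair to make the error actionable
        bad = []
        for i in range(m.shape[1]):
            for j in range(i + 1, m.shape[1]):
                c = abs(np.dot(m[:, i], m[:, j]))
                if c > 1.0 - 1e-8:
                    bad.append(f"{w.names[i]!r}~{w.names[j]!r}")
        detail = ", ".join(bad) if bad else "columns are linearly dependent"
        raise ValueError(f"rank-deficient stain matrix: {detail}")
    pinv = np.linalg.pinv(m)
    conc = od @ pinv.T  # (H, W, k)
    return [conc[..., i] for i in range(m.shape[1])]


def hematoxylin_image(img: np.ndarray, i0: float = 255.0,
                      w: StainMatrix | None = None) -> np.ndarray:
    """RGB image -> hematoxylin concentration image (first stain channel)."""
    return deconvolve(rgb_to_optical_density(img, i0), w)[0]


@dataclass(frozen=True)
class PositionStats:
    """Per-position mean/std over a sample of same-sized patches.

    Standard deviation uses the population (1/N) convention and is floored
    at ``STAIN_STD_FLOOR`` so standardization never divides by zero.
    """

    mean: np.ndarray
    std: np.ndarray
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std shapes differ")
        if np.any(self.std <= 0):
            raise ValueError("std must be positive everywhere (floor applied)")


def fit_position_stats(patches: np.ndarray) -> PositionStats:
    """Fit per-position mean and population std over a patch sample.

    Parameters
    ----------
    patches : (N, s, s) array or sequence of equally shaped 2-D patches.
    """
    arr = np.asarray(patches, dtype=float)
    if arr.ndim != 3:
        shapes = {np.shape(p) for p in patches}
        raise ValueError(f"patches must share one shape, got {sorted(map(str, shapes))}")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 patches to fit statistics")
    mean = arr.mean(axis=0)
    std = np.maximum(arr.std(axis=0), STAIN_STD_FLOOR)
    return PositionStats(mean=mean, std=std, n=arr.shape[0])


def standardize(patch: np.ndarray, stats: PositionStats) -> np.ndarray:
    """Standardize a patch position-wise: ``(x - mean) / std``."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != stats.mean.shape:
        raise ValueError(
            f"patch shape {patch.shape} does not match stats shape {stats.mean.shape}"
        )
    return (patch - stats.mean) / stats.std
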