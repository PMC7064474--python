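"""Synthetic cytological scenes with exact ground truth.

Scenes contain elliptical hematoxylin-dominant nuclei on eosin-dominant
cytoplasm halos over a white background. Ground truth is exact by
construction: a per-nucleus label mask (overlaps resolved by z-order, later
nucleus wins), the full silhouette of every nucleus, and a semantic map
with a 1-px nucleus-border ring. RGB is rendered through the same
Beer-Lambert forward model that the stain module inverts, so the
deconvolution round trip is exact up to quantization and noise.

Semantic palette: 0 indeterminate, 1 background, 2 cytoplasm, 3 nucleus,
4 nucleus border.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import draw
from skimage.morphology import disk

from .morphometrics import STRUCT_8
from .stains import he_imagej_matrix

__all__ = [
    "SEM_INDETERMINATE",
    "SEM_BACKGROUND",
    "SEM_CYTOPLASM",
    "SEM_NUCLEUS",
    "SEM_BORDER",
    "Ellipse",
    "SceneSpec",
    "SyntheticScene",
    "render_transmission",
    "render_rgb",
    "generate_scene",
    "generate_clump",
    "generate_patch_corpus",
    "roughen_boundary",
]

SEM_INDETERMINATE = 0
SEM_BACKGROUND = 1
SEM_CYTOPLASM = 2
SEM_NUCLEUS = 3
SEM_BORDER = 4


@dataclass(frozen=True)
class Ellipse:
    """Rasterizable ellipse: center (row, col), semi-axes, rotation."""

    row: float
    col: float
    a: float
    b: float
    rotation: float = 0.0

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        rr, cc = draw.ellipse(
            self.row, self.col, self.a, self.b, shape=shape, rotation=self.rotation
        )
        mask[rr, cc] = True
        return mask


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    height: int = 512
    width: int = 512
    n_nuclei: int = 30
    radius_range: tuple[float, float] = (12.0, 26.0)
    # min ratio 1.25 keeps digital-ellipse roundness below the 0.99 gate
    axis_ratio_range: tuple[float, float] = (1.25, 1.6)
    overlap_fraction: float = 0.0
    nucleus_h: float = 1.0
    nucleus_h_jitter: tuple[float, float] = (0.85, 1.15)
    nucleus_e: float = 0.2
    border_h_scale: float = 1.1
    cytoplasm_h: float = 0.15
    cytoplasm_e: float = 0.7
    cytoplasm_halo: int = 6
    noise_sd: float = 4.0
    i0: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius range")
        if self.n_nuclei < 0 or self.height < 1 or self.width < 1:
            raise ValueError("invalid scene geometry")


@dataclass
class SyntheticScene:
    rgb: np.ndarray
    labels: np.ndarray
    semantic: np.ndarray
    ellipses: list[Ellipse]
    silhouettes: list[np.ndarray] = field(default_factory=list)
    h_conc: np.ndarray | None = None
    e_conc: np.ndarray | None = None
    spec: SceneSpec | None = None

    @property
    def nuclei_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def interior_mask(self) -> np.ndarray:
        """Oracle nuclei mask: interiors only, border ring excluded (the
        ground-truth analog of a perfect semantic prediction)."""
        return self.semantic == SEM_NUCLEUS

    @property
    def hematoxylin_truth(self) -> np.ndarray:
        """Planted hematoxylin concentration map (no noise)."""
        return self.h_conc


def render_transmission(h_conc: np.ndarray, e_conc: np.ndarray,
                        i0: float = 255.0) -> np.ndarray:
    """Noise-free, unquantized forward Beer-Lambert rendering (float RGB).

    ``I = i0 * 10**-(W @ C)`` with the default H&E stain matrix and zero
    residual concentration.
    """
    w = he_imagej_matrix().matrix
    conc = np.stack([h_conc, e_conc, np.zeros_like(h_conc)], axis=-1)
    absorbance = conc @ w.T
    return float(i0) * np.power(10.0, -absorbance)


def render_rgb(h_conc: np.ndarray, e_conc: np.ndarray, noise_sd: float = 0.0,
               i0: float = 255.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Quantized 8-bit rendering with optional Gaussian intensity noise."""
    img = render_transmission(h_conc, e_conc, i0)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _chain_ellipses(k: int, rng: np.random.Generator, radius_range, axis_ratio_range,
                    spread: tuple[float, float] = (0.80, 0.95)) -> list[Ellipse]:
    """A chain of k mutually overlapping ellipses around the origin.

    Center spacing is 0.80-0.95 of the sum of the pair's mean radii, which
    keeps each pair overlapped yet separable (centers stay at least 1.2x
    the mean radius apart for the supported radius range).
    """
    r0 = rng.uniform(*radius_range)
    members: list[Ellipse] = []
    pos = np.zeros(2)
    heading = rng.uniform(0, 2 * np.pi)
    prev_r = 0.0
    for i in range(k):
        ratio = rng.uniform(*axis_ratio_range)
        mean_r = r0 * rng.uniform(0.85, 1.15)
        a = mean_r * np.sqrt(ratio)
        b = mean_r / np.sqrt(ratio)
        if i > 0:
            d = rng.uniform(*spread) * (prev_r + mean_r)
            heading += rng.uniform(-np.pi / 3, np.pi / 3)
            pos = pos + d * np.array([np.sin(heading), np.cos(heading)])
        members.append(Ellipse(pos[0], pos[1], a, b, rng.uniform(0, np.pi)))
        prev_r = mean_r
    return members


def generate_clump(
    k: int,
    radius_range: tuple[float, float] = (12.0, 30.0),
    axis_ratio_range: tuple[float, float] = (1.0, 1.0),
    seed: int | np.random.Generator = 0,
    max_tries: int = 50,
) -> tuple[np.ndarray, int, list[Ellipse]]:
    """Generate one connected blob of ``k`` overlapping ellipses.

    Returns the binary blob, the true count ``k`` and the member ellipses
    (coordinates on the returned canvas).
    """
    if k < 2:
        raise ValueError("a clump needs k >= 2 nuclei")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    extent = int(2 * radius_range[1] * max(axis_ratio_range) * (k + 1)) + 8
    shape = (extent, extent)
    for _ in range(max_tries):
        members = _chain_ellipses(k, rng, radius_range, axis_ratio_range)
        rows = np.array([m.row for m in members])
        cols = np.array([m.col for m in members])
        shift_r = extent / 2 - rows.mean()
        shift_c = extent / 2 - cols.mean()
        members = [
            replace(m, row=m.row + shift_r, col=m.col + shift_c) for m in members
        ]
        mask = np.zeros(shape, dtype=bool)
        ok = True
        for m in members:
            sil = m.raster(shape)
            if sil[0].any() or sil[-1].any() or sil[:, 0].any() or sil[:, -1].any():
                ok = False
                break
            mask |= sil
        if not ok:
            continue
        _, n = ndimage.label(mask, structure=STRUCT_8)
        if n == 1:
            return mask, k, members
    raise RuntimeError(f"failed to build a connected {k}-clump in {max_tries} tries")


def roughen_boundary(mask: np.ndarray, n_notches: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Carve single-pixel notches into a blob contour (jagged-mask model).

    Used to emulate the ragged outlines of thresholding-based masks, which
    seed spurious distance-transform maxima.
    """
    out = np.asarray(mask).astype(bool).copy()
    for _ in range(n_notches):
        contour = out & ~ndimage.binary_erosion(out, structure=STRUCT_8)
        pts = np.argwhere(contour)
        if len(pts) == 0:
            break
        y, x = pts[rng.integers(len(pts))]
        out[y, x] = False
    # keep only the largest component in case a notch pinched something off
    labels, n = ndimage.label(out, structure=STRUCT_8)
    if n > 1:
        sizes = ndimage.sum_labels(out, labels, index=range(1, n + 1))
        out = labels == (1 + int(np.argmax(sizes)))
    return out


def interface_border_mask(labels: np.ndarray, semantic: np.ndarray) -> np.ndarray:
    """Border pixels lying on interfaces between two nuclei (inside clumps).

    These are rare compared to outer-rim border pixels but are exactly the
    ones that let the mask keep touching nuclei apart, so the patch corpus
    oversamples them.
    """
    labels = np.asarray(labels)
    border = np.asarray(semantic) == SEM_BORDER
    internal = np.zeros_like(border)
    for lab in range(1, int(labels.max()) + 1):
        region = labels == lab
        if not region.any():
            continue
        other = (labels > 0) & ~region
        internal |= region & ndimage.binary_dilation(other, structure=STRUCT_8)
    return internal & border


def _clump_plan(n: int, overlap_fraction: float) -> list[int]:
    """Split n nuclei into clump sizes (2 or 3) plus singletons so that the
    fraction of nuclei belonging to a clump hits the target."""
    t = int(round(overlap_fraction * n))
    if t == 1:
        t = 2 if n >= 2 else 0
    sizes: list[int] = []
    while t >= 2:
        k = 3 if t % 2 == 1 else 2
        sizes.append(k)
        t -= k
    sizes.extend([1] * (n - sum(sizes)))
    return sizes


def generate_scene(spec: SceneSpec, max_tries: int = 200) -> SyntheticScene:
    """Generate one scene: place nuclei (singletons and planned clumps),
    build ground truth, render RGB."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    occupied = np.zeros(shape, dtype=bool)
    ellipses: list[Ellipse] = []
    silhouettes: list[np.ndarray] = []

    for k in _clump_plan(spec.n_nuclei, spec.overlap_fraction):
        placed = False
        for _ in range(max_tries):
            if k == 1:
                ratio = rng.uniform(*spec.axis_ratio_range)
                r = rng.uniform(*spec.radius_range)
                members = [
                    Ellipse(0.0, 0.0, r * np.sqrt(ratio), r / np.sqrt(ratio),
                            rng.uniform(0, np.pi))
                ]
            else:
                members = _chain_ellipses(
                    k, rng, spec.radius_range, spec.axis_ratio_range
                )
            pad = spec.radius_range[1] * max(spec.axis_ratio_range) + 2
            row0 = rng.uniform(pad, spec.height - pad)
            col0 = rng.uniform(pad, spec.width - pad)
            rows = np.array([m.row for m in members])
            cols = np.array([m.col for m in members])
            members = [
                replace(m, row=m.row - rows.mean() + row0,
                        col=m.col - cols.mean() + col0)
                for m in members
            ]
            sils = [m.raster(shape) for m in members]
            union = np.logical_or.reduce(sils)
            if union[0].any() or union[-1].any() or union[:, 0].any() or union[:, -1].any():
                continue
            _, ncomp = ndimage.label(union, structure=STRUCT_8)
            if ncomp != 1:
                continue
            grown = ndimage.binary_dilation(union, structure=disk(3))
            if (grown & occupied).any():
                continue
            occupied |= grown
            ellipses.extend(members)
            silhouettes.extend(sils)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place all nuclei; reduce n_nuclei or enlarge the canvas"
            )

    labels = np.zeros(shape, dtype=np.int32)
    for i, sil in enumerate(silhouettes, start=1):  # z-order: later wins
        labels[sil] = i

    semantic = np.full(shape, SEM_BACKGROUND, dtype=np.uint8)
    if silhouettes:
        union = labels > 0
        halo = ndimage.binary_dilation(union, structure=disk(spec.cytoplasm_halo))
        semantic[halo & ~union] = SEM_CYTOPLASM
        semantic[union] = SEM_NUCLEUS
        # 1-px border ring per nucleus region of the resolved label mask,
        # including internal boundaries between overlapping nuclei
        for lab in range(1, len(silhouettes) + 1):
            region = labels == lab
            if not region.any():
                continue
            interior = ndimage.binary_erosion(region, structure=STRUCT_8,
                                              border_value=0)
            semantic[region & ~interior] = SEM_BORDER

    h_conc = np.zeros(shape, dtype=float)
    e_conc = np.zeros(shape, dtype=float)
    h_conc[semantic == SEM_CYTOPLASM] = spec.cytoplasm_h
    e_conc[semantic == SEM_CYTOPLASM] = spec.cytoplasm_e
    jitters = rng.uniform(*spec.nucleus_h_jitter, size=len(silhouettes))
    for lab in range(1, len(silhouettes) + 1):
        region = labels == lab
        if not region.any():
            continue
        nh = spec.nucleus_h * jitters[lab - 1]
        h_conc[region] = nh
        e_conc[region] = spec.nucleus_e
        h_conc[region & (semantic == SEM_BORDER)] = nh * spec.border_h_scale
    rgb = render_rgb(h_conc, e_conc, spec.noise_sd, spec.i0, rng)
    return SyntheticScene(rgb, labels, semantic, ellipses, silhouettes,
                          h_conc, e_conc, spec)


def generate_patch_corpus(
    scenes: list[SyntheticScene],
    hematoxylin: list[np.ndarray],
    size: int = 43,
    n_per_class_per_scene: int = 250,
    n_interface_per_scene: int | None = None,
    val_fraction: float = 0.5,
    seed: int = 0,
) -> dict:
    """Build balanced labeled patch sets from scenes, split scene-wise.

    ``hematoxylin[i]`` is the hematoxylin concentration image of scene i
    (typically obtained by deconvolving the rendered RGB). No scene
    contributes patches to both splits. Border patches from nucleus-nucleus
    interfaces are oversampled (``n_interface_per_scene`` extra, default
    equal to ``n_per_class_per_scene``) because they are scarce yet decide
    whether touching nuclei stay separated.
    """
    from .semantic import CLASS_NAMES, extract_patches, semantic_to_class

    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    if len(scenes) != len(hematoxylin):
        raise ValueError("one hematoxylin image per scene required")
    if len(scenes) < 2:
        raise ValueError("need at least 2 scenes for a scene-wise split")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_fraction * len(scenes))))
    order = rng.permutation(len(scenes))
    val_ids = set(order[:n_val].tolist())

    if n_interface_per_scene is None:
        n_interface_per_scene = n_per_class_per_scene
    splits = {"train": ([], []), "val": ([], [])}
    for i, (scene, hchan) in enumerate(zip(scenes, hematoxylin)):
        which = "val" if i in val_ids else "train"
        classes = semantic_to_class(scene.semantic)
        for cls in range(len(CLASS_NAMES)):
            pts = np.argwhere(classes == cls)
            if len(pts) == 0:
                raise ValueError(
                    f"scene {i} has no pixels of class {CLASS_NAMES[cls]!r}"
                )
            take = pts[
                rng.choice(len(pts), size=min(n_per_class_per_scene, len(pts)),
                           replace=False)
            ]
            if cls == 1 and n_interface_per_scene > 0:
                iface = np.argwhere(
                    interface_border_mask(scene.labels, scene.semantic)
                )
                if len(iface):
                    extra = iface[
                        rng.choice(len(iface), size=n_interface_per_scene,
                                   replace=True)
                    ]
                    take = np.concatenate([take, extra])
            patches, labels, _ = extract_patches(
                hchan, scene.semantic, size=size, positions=take
            )
            splits[which][0].append(patches)
            splits[which][1].append(labels)

    out = {}
    for which, (ps, ls) in splits.items():
        if not ps:
            raise ValueError(f"{which} split received no scenes")
        out[f"{which}_patches"] = np.concatenate(ps, axis=0)
        out[f"{which}_labels"] = np.concatenate(ls, axis=0)
    out["val_scene_ids"] = sorted(val_ids)
    return out
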