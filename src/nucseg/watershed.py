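"""Seeded watershed separation of nucleus clumps.

The topographic surface is the exact Euclidean distance transform of the
nuclei mask. Seeds found by conditional erosion are imposed on it by
grayscale morphological reconstruction (iterated geodesic dilation of the
seed-restricted map under the full map), which flattens every regional
maximum that contains no seed. Basins are then flooded from the seeds with
a Meyer-style priority queue; watershed-line pixels go to the
first-arriving basin (FIFO on equal priority), so basins partition the
mask and the region count equals the seed-component count.

``run_pipeline`` chains the full method: nuclei mask -> connected objects
-> morphometric gating -> per-clump seeding + flooding -> re-gating ->
aggregation of accepted nuclei.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morphometrics import (
    STRUCT_4,
    STRUCT_8,
    GatingRule,
    MorphometricRecord,
    ObjectClass,
    classify_object,
    label_components,
    measure,
)
from .seeds import COARSE_SE, FINE_SE, ErosionPolicy, conditional_erode

__all__ = [
    "distance_map",
    "geodesic_dilate",
    "reconstruct",
    "impose_seeds",
    "flood",
    "local_maxima_seeds",
    "SegmentationResult",
    "run_pipeline",
]

_CROSS = STRUCT_4  # 4-connected elementary dilation footprint


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each foreground pixel to the nearest
    background pixel. Pixels outside the image do not count as background."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=float)
    if mask.all():
        # no background inside the canvas: pad so the border acts as one
        padded = np.pad(mask, 1, constant_values=False)
        return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return ndimage.distance_transform_edt(mask)


def geodesic_dilate(marker: np.ndarray, mask_img: np.ndarray,
                    footprint: np.ndarray = _CROSS) -> np.ndarray:
    """Elementary geodesic dilation: ``min(dilate(marker), mask_img)``."""
    marker = np.asarray(marker, dtype=float)
    mask_img = np.asarray(mask_img, dtype=float)
    if marker.shape != mask_img.shape:
        raise ValueError("marker and mask images must share a shape")
    if np.any(marker > mask_img + 1e-12):
        raise ValueError("marker must be <= mask image everywhere")
    dil = ndimage.grey_dilation(marker, footprint=footprint)
    return np.minimum(dil, mask_img)


def reconstruct(marker: np.ndarray, mask_img: np.ndarray,
                footprint: np.ndarray = _CROSS) -> np.ndarray:
    """Morphological reconstruction by dilation: iterate the elementary
    geodesic dilation until stability."""
    current = np.asarray(marker, dtype=float)
    mask_img = np.asarray(mask_img, dtype=float)
    if current.shape != mask_img.shape:
        raise ValueError("marker and mask images must share a shape")
    if np.any(current > mask_img + 1e-12):
        raise ValueError("marker must be <= mask image everywhere")
    while True:
        nxt = np.minimum(ndimage.grey_dilation(current, footprint=footprint), mask_img)
        if np.array_equal(nxt, current):
            return nxt
        current = nxt


def impose_seeds(tm: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Suppress every regional maximum of ``tm`` that contains no seed.

    The marker keeps the topographic height at seed pixels and is zero
    elsewhere; the result is its reconstruction under ``tm``.
    """
    tm = np.asarray(tm, dtype=float)
    seeds = np.asarray(seeds).astype(bool)
    if tm.shape != seeds.shape:
        raise ValueError("seed mask and topographic map must share a shape")
    if not seeds.any():
        raise ValueError("seed mask is empty")
    outside = seeds & (tm <= 0)
    if outside.any():
        labels, _ = ndimage.label(seeds, structure=STRUCT_8)
        bad = sorted(int(v) for v in np.unique(labels[outside]) if v)
        raise ValueError(f"seed component(s) {bad} lie outside the mask (zero height)")
    marker = np.where(seeds, tm, 0.0)
    return reconstruct(marker, tm)


def _label_seeds(seeds: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(np.asarray(seeds).astype(bool), structure=STRUCT_8)
    return labels.astype(np.int32), n


def flood(tm: np.ndarray, seeds: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flood basins of ``-tm`` from the seed components, restricted to
    ``mask``.

    Growth is 4-connected. Equal priorities are resolved first-in
    first-out, and watershed-line pixels are claimed by the first-arriving
    basin, so the basins partition the reachable mask. Mask components
    containing no seed are left unlabeled.
    """
    tm = np.asarray(tm, dtype=float)
    mask = np.asarray(mask).astype(bool)
    seed_labels, n = _label_seeds(np.asarray(seeds).astype(bool) & mask)
    if n == 0:
        raise ValueError("seed mask is empty (or lies outside the mask)")
    out = np.where(mask, seed_labels, 0).astype(np.int32)
    h, w = tm.shape
    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    ys, xs = np.nonzero(seed_labels)
    order = np.lexsort((xs, ys))  # deterministic raster-order enqueueing
    for i in order:
        y, x = int(ys[i]), int(xs[i])
        heapq.heappush(heap, (-tm[y, x], counter, y, x, int(seed_labels[y, x])))
        counter += 1
    while heap:
        _, _, y, x, lab = heapq.heappop(heap)
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and out[ny, nx] == 0:
                out[ny, nx] = lab
                heapq.heappush(heap, (-tm[ny, nx], counter, ny, nx, lab))
                counter += 1
    return out


def local_maxima_seeds(tm: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Regional maxima of the topographic map — the classical (unseeded)
    watershed seed choice the conditional-erosion seeding replaces."""
    from skimage.morphology import local_maxima

    tm = np.asarray(tm, dtype=float)
    maxima = local_maxima(tm, connectivity=2)
    if mask is not None:
        maxima &= np.asarray(mask).astype(bool)
    else:
        maxima &= tm > 0
    return maxima


@dataclass
class SegmentationResult:
    """Final segmentation: accepted nuclei plus per-object provenance."""

    accepted: np.ndarray
    provenance: dict[int, str] = field(default_factory=dict)
    records: dict[int, MorphometricRecord] = field(default_factory=dict)
    rejected_clumps: list[int] = field(default_factory=list)
    n_debris: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.provenance)


def _separate_clump(clump: np.ndarray, policy: ErosionPolicy,
                    mc=COARSE_SE, mf=FINE_SE) -> np.ndarray:
    """Seed and flood one clump; returns a label image on the clump canvas."""
    seeds = conditional_erode(clump, policy, mc, mf)
    tm = distance_map(clump)
    tm_imposed = impose_seeds(tm, seeds)
    return flood(tm_imposed, seeds, clump)


def run_pipeline(
    stain: np.ndarray | None = None,
    mask_method: str = "otsu",
    model=None,
    *,
    mask: np.ndarray | None = None,
    gating: GatingRule | None = None,
    erosion: ErosionPolicy | None = None,
    adaptive_window: int = 51,
    adaptive_offset: float = 0.0,
) -> SegmentationResult:
    """Run the full segmentation chain on one image.

    Parameters
    ----------
    stain : hematoxylin concentration image (required unless ``mask`` given)
    mask_method : 'cnn' | 'otsu' | 'adaptive' | 'given'
    model : trained patch classifier, required iff mask_method == 'cnn'
    mask : precomputed binary nuclei mask for mask_method == 'given'
    """
    from . import semantic

    gating = gating or GatingRule()
    erosion = erosion or ErosionPolicy()

    try:
        if mask_method == "given":
            if mask is None:
                raise ValueError("mask_method 'given' requires a mask")
            nuclei_mask = np.asarray(mask).astype(bool)
        elif mask_method == "otsu":
            nuclei_mask = semantic.mask_otsu(stain)
        elif mask_method == "adaptive":
            nuclei_mask = semantic.mask_adaptive(stain, adaptive_window, adaptive_offset)
        elif mask_method == "cnn":
            if model is None:
                raise ValueError("mask_method 'cnn' requires a trained model")
            smap, _ = semantic.predict_semantic_map(model, stain)
            nuclei_mask = semantic.mask_from_semantic(smap)
        else:
            raise ValueError(f"unknown mask method {mask_method!r}")
    except Exception as exc:
        raise type(exc)(f"[mask stage] {exc}") from exc

    labels = label_components(nuclei_mask)
    result = SegmentationResult(accepted=np.zeros(labels.shape, dtype=np.int32))
    next_label = 1
    slices = ndimage.find_objects(labels)
    for rec in measure(labels):
        cls = classify_object(rec, gating)
        if cls is ObjectClass.DEBRIS:
            result.n_debris += 1
            continue
        sl = slices[rec.label - 1]
        # 1-px background margin around the clump bounding box
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, labels.shape)
        )
        obj = labels[sl] == rec.label
        if cls is ObjectClass.SINGLE:
            result.accepted[sl][obj] = next_label
            result.provenance[next_label] = "direct"
            result.records[next_label] = MorphometricRecord(
                next_label, rec.area, rec.perimeter, rec.roundness
            )
            next_label += 1
            continue
        # clump: seed, flood, re-gate the fragments
        try:
            frag_labels = _separate_clump(obj, erosion)
        except Exception as exc:
            raise type(exc)(f"[separation stage, object {rec.label}] {exc}") from exc
        accepted_any = False
        for frec in measure(frag_labels):
            fcls = classify_object(frec, gating)
            if fcls is ObjectClass.SINGLE:
                frag = frag_labels == frec.label
                result.accepted[sl][frag] = next_label
                result.provenance[next_label] = "watershed"
                result.records[next_label] = MorphometricRecord(
                    next_label, frec.area, frec.perimeter, frec.roundness
                )
                next_label += 1
                accepted_any = True
        if not accepted_any:
            result.rejected_clumps.append(rec.label)
    return result
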