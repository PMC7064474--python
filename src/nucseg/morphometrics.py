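"""Connected-component labeling, shape measurement and object gating.

Objects in the binary nuclei mask are labeled, measured (area, perimeter,
roundness) and classified as single nucleus, clump of overlapping nuclei,
or debris. The gates default to the empirical single-nucleus ranges:
area 309..7801 px, roundness 0.31..0.99.

Roundness is ``4 * pi * area / perimeter**2`` (1.0 for a perfect circle).
The perimeter is the Crofton 4-direction estimator; plain pixel-edge
counting would overestimate perimeters and push round objects below the
printed roundness range. With this estimator the roundness of digital
shapes can exceed 1: by up to ~8% (epsilon = 0.08) for small blobs
(~100 px), well under 1% at nucleus scale (>= 300 px).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton

__all__ = [
    "GatingRule",
    "MorphometricRecord",
    "ObjectClass",
    "label_components",
    "measure",
    "classify_object",
]

STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
STRUCT_8 = np.ones((3, 3), dtype=bool)


class ObjectClass(str, Enum):
    SINGLE = "single"
    CLUMP = "clump"
    DEBRIS = "debris"


@dataclass(frozen=True)
class GatingRule:
    """Acceptance window for a single nucleus."""

    area_min: float = 309.0
    area_max: float = 7801.0
    roundness_min: float = 0.31
    roundness_max: float = 0.99

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be < area_max")
        if not self.roundness_min < self.roundness_max:
            raise ValueError("roundness_min must be < roundness_max")


@dataclass(frozen=True)
class MorphometricRecord:
    label: int
    area: float
    perimeter: float
    roundness: float


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected foreground components 1..N in raster-scan order.

    Parameters
    ----------
    mask : binary (H, W) array
    connectivity : 4 or 8 (default 8)
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    structure = STRUCT_8 if connectivity == 8 else STRUCT_4
    labels, _ = ndimage.label(mask, structure=structure)
    return labels.astype(np.int32)


def measure(labels: np.ndarray) -> list[MorphometricRecord]:
    """Measure area, Crofton perimeter and roundness for every object."""
    labels = np.asarray(labels)
    n = int(labels.max())
    records: list[MorphometricRecord] = []
    if n == 0:
        return records
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        if sl is None:
            continue
        obj = labels[sl] == lab
        area = float(obj.sum())
        perim = float(perimeter_crofton(obj, directions=4))
        if perim <= 0:  # sub-resolution object (single pixel rounding)
            perim = 1.0
        roundness = 4.0 * np.pi * area / perim**2
        records.append(MorphometricRecord(lab, area, perim, roundness))
    return records


def classify_object(rec: MorphometricRecord,
                    rule: GatingRule | None = None) -> ObjectClass:
    """Gate an object: single if inside both windows, debris if too small,
    otherwise a clump (too large or too irregular)."""
    rule = rule or GatingRule()
    if rec.area < rule.area_min:
        return ObjectClass.DEBRIS
    in_area = rule.area_min <= rec.area <= rule.area_max
    in_round = rule.roundness_min <= rec.roundness <= rule.roundness_max
    if in_area and in_round:
        return ObjectClass.SINGLE
    return ObjectClass.CLUMP
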