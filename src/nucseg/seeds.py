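"""Seed detection inside nucleus clumps by two-phase conditional erosion.

A clump is eroded with a coarse 7x7 octagonal element while its components
stay at or above T1 pixels, then with a fine 3x3 cross until every
component drops below T2. Components are re-identified after every erosion
pass, so one blob may split into several seeds, each then eroded
independently. A component whose next erosion would empty it is frozen at
its last non-empty state, so every input component yields at least one seed.

Defaults: T1 = 350, T2 = 50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphometrics import STRUCT_8

__all__ = [
    "StructuringElement",
    "ErosionPolicy",
    "COARSE_SE",
    "FINE_SE",
    "erode",
    "conditional_erode",
]


@dataclass(frozen=True)
class StructuringElement:
    """Odd-sided binary structuring element with its origin at the center."""

    footprint: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint).astype(bool)
        if fp.ndim != 2 or any(s % 2 == 0 for s in fp.shape):
            raise ValueError("structuring element must be 2-D with odd side lengths")
        if not fp.any():
            raise ValueError("structuring element must contain at least one pixel")
        if not fp[fp.shape[0] // 2, fp.shape[1] // 2]:
            raise ValueError("origin pixel of the structuring element must be set")
        object.__setattr__(self, "footprint", fp)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "StructuringElement":
        return cls(np.loadtxt(path, delimiter=",") > 0.5, name or str(path))


#: 7x7 octagon, 23 pixels — coarse erosion element.
COARSE_SE = StructuringElement(
    np.array(
        [
            [0, 0, 0, 1, 0, 0, 0],
            [0, 0, 1, 1, 1, 0, 0],
            [0, 1, 1, 1, 1, 1, 0],
            [0, 1, 1, 1, 1, 1, 0],
            [0, 1, 1, 1, 1, 1, 0],
            [0, 0, 1, 1, 1, 0, 0],
            [0, 0, 0, 1, 0, 0, 0],
        ]
    ),
    "coarse_octagon_7x7",
)

#: 3x3 cross, 5 pixels — fine erosion element.
FINE_SE = StructuringElement(
    np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]), "fine_cross_3x3"
)


@dataclass(frozen=True)
class ErosionPolicy:
    """Area thresholds: coarse phase while area >= t1, fine while >= t2."""

    t1: int = 350
    t2: int = 50

    def __post_init__(self) -> None:
        if not self.t1 > self.t2 > 0:
            raise ValueError("thresholds must satisfy t1 > t2 > 0")


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion: keep a pixel iff the SE translated there fits in the
    mask. Outside the image counts as background (objects shrink inward at
    borders)."""
    mask = np.asarray(mask).astype(bool)
    return ndimage.binary_erosion(mask, structure=se.footprint, border_value=0)


def _components(mask: np.ndarray) -> list[np.ndarray]:
    labels, n = ndimage.label(mask, structure=STRUCT_8)
    return [labels == i for i in range(1, n + 1)]


def conditional_erode(
    clump: np.ndarray,
    policy: ErosionPolicy | None = None,
    mc: StructuringElement = COARSE_SE,
    mf: StructuringElement = FINE_SE,
) -> np.ndarray:
    """Reduce each clump component to one small seed per nucleus.

    Returns a binary seed mask, a pixelwise subset of ``clump``.
    """
    policy = policy or ErosionPolicy()
    clump = np.asarray(clump).astype(bool)
    out = np.zeros_like(clump)
    work = _components(clump)
    while work:
        comp = work.pop()
        area = int(comp.sum())
        if area == 0:
            continue
        se = mc if area >= policy.t1 else mf if area >= policy.t2 else None
        if se is None:
            out |= comp
            continue
        eroded = erode(comp, se)
        if not eroded.any():
            # vanish protection: keep the last non-empty state as the seed
            out |= comp
            continue
        work.extend(_components(eroded))
    return out
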