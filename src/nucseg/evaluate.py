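"""Object-level segmentation accuracy: Hausdorff/Jaccard matching protocol.

Reference and predicted nuclei are compared as pixel sets. A full
reference x predicted distance matrix is built under one metric, pairs are
matched greedily from the globally smallest distance up, one-to-one, and
any pair beyond the threshold stays unmatched. Matched references are TP,
unmatched references FN, unmatched predictions FP. Default thresholds:
Hausdorff 30 px, Jaccard 0.5.

Hausdorff distances are computed over the full object pixel sets, not the
contours. fp_rate uses ``|predicted|`` as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "hausdorff",
    "jaccard_distance",
    "objects_from_labels",
    "match",
    "MatchReport",
    "summarize",
]

HD_THRESHOLD = 30.0
JD_THRESHOLD = 0.5


def _coords(mask: np.ndarray) -> np.ndarray:
    pts = np.argwhere(np.asarray(mask).astype(bool))
    if pts.size == 0:
        raise ValueError("object mask is empty")
    return pts.astype(float)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two object pixel sets."""
    pa, pb = _coords(a), _coords(b)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |a & b| / |a | b| over two object masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if not a.any() or not b.any():
        raise ValueError("object mask is empty")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return 1.0 - inter / union


def objects_from_labels(labels: np.ndarray) -> list[np.ndarray]:
    """Split a label image into per-object boolean masks (label order)."""
    labels = np.asarray(labels)
    return [labels == lab for lab in np.unique(labels) if lab != 0]


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return ys.min(), ys.max(), xs.min(), xs.max()


def _bbox_gap(b1, b2) -> float:
    dy = max(b1[0] - b2[1], b2[0] - b1[1], 0)
    dx = max(b1[2] - b2[3], b2[2] - b1[3], 0)
    return float(np.hypot(dy, dx))


@dataclass
class MatchReport:
    """One-to-one matching outcome under a single metric and threshold."""

    metric: str
    threshold: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def tp_rate(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fp_rate(self) -> float:
        n_pred = self.tp + self.fp
        return self.fp / n_pred if n_pred else 0.0


def match(
    reference: list[np.ndarray],
    predicted: list[np.ndarray],
    metric: str = "jaccard",
    threshold: float | None = None,
) -> MatchReport:
    """Match reference against predicted objects, nearest pairs first.

    Distances for pairs whose bounding boxes are farther apart than the
    Hausdorff threshold (or disjoint, for Jaccard) are never below
    threshold, so they are skipped without being computed.
    """
    if metric not in ("hausdorff", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    if threshold is None:
        threshold = HD_THRESHOLD if metric == "hausdorff" else JD_THRESHOLD
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not reference:
        raise ValueError("reference object set is empty; rates are undefined")
    dist_fn = hausdorff if metric == "hausdorff" else jaccard_distance
    ref_boxes = [_bbox(m) for m in reference]
    pred_boxes = [_bbox(m) for m in predicted]
    candidates: list[tuple[float, int, int]] = []
    for i, (rm, rb) in enumerate(zip(reference, ref_boxes)):
        for j, (pm, pb) in enumerate(zip(predicted, pred_boxes)):
            gap = _bbox_gap(rb, pb)
            if metric == "hausdorff" and gap > threshold:
                continue
            if metric == "jaccard" and gap > 0:
                continue  # disjoint boxes -> JD = 1 > any valid threshold
            d = dist_fn(rm, pm)
            if d <= threshold:
                candidates.append((d, i, j))
    candidates.sort()
    used_ref: set[int] = set()
    used_pred: set[int] = set()
    report = MatchReport(metric=metric, threshold=float(threshold))
    for d, i, j in candidates:
        if i in used_ref or j in used_pred:
            continue
        used_ref.add(i)
        used_pred.add(j)
        report.pairs.append((i, j, d))
    report.tp = len(report.pairs)
    report.fn = len(reference) - report.tp
    report.fp = len(predicted) - report.tp
    return report


def summarize(reports: list[MatchReport],
              groups: list[str] | None = None) -> pd.DataFrame:
    """Per-group mean/sd/max/min of TP and FP rates over a set of reports.

    Standard deviation is the sample (ddof=1) convention; a single-report
    group gets sd 0.
    """
    if not reports:
        raise ValueError("need at least one report")
    if groups is None:
        groups = ["all"] * len(reports)
    if len(groups) != len(reports):
        raise ValueError("one group label per report required")
    df = pd.DataFrame(
        {
            "group": groups,
            "metric": [r.metric for r in reports],
            "tp_rate": [r.tp_rate for r in reports],
            "fp_rate": [r.fp_rate for r in reports],
        }
    )
    out = (
        df.groupby(["metric", "group"])[["tp_rate", "fp_rate"]]
        .agg(["mean", "std", "max", "min"])
        .fillna(0.0)
    )
    out.columns = [f"{rate}_{stat}" for rate, stat in out.columns]
    return out.reset_index()
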