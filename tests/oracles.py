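"""Independent brute-force oracles used to check the library implementations.

Everything here is deliberately naive (loops, exhaustive search, direct
definitions) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def erosion_oracle(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary erosion by definition: SE translated to the pixel must fit."""
    mask = np.asarray(mask).astype(bool)
    se = np.asarray(se).astype(bool)
    h, w = mask.shape
    cy, cx = se.shape[0] // 2, se.shape[1] // 2
    offs = [(i - cy, j - cx) for i, j in np.argwhere(se)]
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            keep = True
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                    keep = False
                    break
            out[y, x] = keep
    return out


def edt_oracle(mask: np.ndarray) -> np.ndarray:
    """O(N^2) exact Euclidean distance to the nearest background pixel."""
    mask = np.asarray(mask).astype(bool)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    if len(fg) == 0:
        return out
    if len(bg) == 0:
        raise ValueError("no background pixel")
    for y, x in fg:
        d2 = (bg[:, 0] - y) ** 2 + (bg[:, 1] - x) ** 2
        out[y, x] = np.sqrt(d2.min())
    return out


def geodesic_fixpoint_oracle(marker: np.ndarray, mask_img: np.ndarray) -> np.ndarray:
    """Iterate elementary 4-connected geodesic dilation until stability."""
    cur = np.asarray(marker, dtype=float).copy()
    mask_img = np.asarray(mask_img, dtype=float)
    h, w = cur.shape
    while True:
        nxt = cur.copy()
        for y in range(h):
            for x in range(w):
                m = cur[y, x]
                if y > 0:
                    m = max(m, cur[y - 1, x])
                if y < h - 1:
                    m = max(m, cur[y + 1, x])
                if x > 0:
                    m = max(m, cur[y, x - 1])
                if x < w - 1:
                    m = max(m, cur[y, x + 1])
                nxt[y, x] = min(m, mask_img[y, x])
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def hausdorff_oracle(a_pts: np.ndarray, b_pts: np.ndarray) -> float:
    """Double-loop Hausdorff distance over two point sets."""

    def directed(p, q):
        worst = 0.0
        for x in p:
            best = min(float(np.hypot(x[0] - y[0], x[1] - y[1])) for y in q)
            worst = max(worst, best)
        return worst

    return max(directed(a_pts, b_pts), directed(b_pts, a_pts))


def flood_fill_count_oracle(mask: np.ndarray, connectivity: int = 8) -> int:
    """Count connected components by explicit BFS flood fill."""
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    count = 0
    for y0, x0 in np.argwhere(mask):
        if seen[y0, x0]:
            continue
        count += 1
        stack = [(int(y0), int(x0))]
        seen[y0, x0] = True
        while stack:
            y, x = stack.pop()
            for dy, dx in nbrs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                    seen[yy, xx] = True
                    stack.append((yy, xx))
    return count


def best_assignment_tp_oracle(dist: np.ndarray, threshold: float) -> int:
    """Maximum number of one-to-one pairs with distance <= threshold,
    by exhaustive enumeration (feasible for <= ~6 per side)."""
    n_ref, n_pred = dist.shape
    k = min(n_ref, n_pred)
    best = 0
    ref_idx = range(n_ref)
    for size in range(k, 0, -1):
        if size <= best:
            break
        for refs in itertools.combinations(ref_idx, size):
            for preds in itertools.permutations(range(n_pred), size):
                if all(dist[r, p] <= threshold for r, p in zip(refs, preds)):
                    best = max(best, size)
                    break
            if best == size:
                break
    return best
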