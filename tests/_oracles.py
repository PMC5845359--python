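"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (BFS labeling, exhaustive threshold
search, ray casting, KD-tree distance queries) and shares no code path with
the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial import cKDTree


def bfs_label(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, list[int]]:
    """Connected-component labeling by breadth-first search; returns (labels, sizes)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    sizes: list[int] = []
    h, w = mask.shape
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    next_label = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            next_label += 1
            size = 0
            queue = deque([(r0, c0)])
            labels[r0, c0] = next_label
            while queue:
                r, c = queue.popleft()
                size += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                        labels[rr, cc] = next_label
                        queue.append((rr, cc))
            sizes.append(size)
    return labels, sizes


def bfs_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions (4-connected) that do not touch the image border."""
    mask = np.asarray(mask, dtype=bool)
    labels, _ = bfs_label(~mask, connectivity=4)
    border_labels = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    filled = mask.copy()
    for label in range(1, labels.max() + 1):
        if label not in border_labels:
            filled |= labels == label
    return filled


def exhaustive_otsu(values: np.ndarray) -> float:
    """Otsu threshold by exhaustive search over 256 candidate levels."""
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = values.min(), values.max()
    candidates = np.linspace(lo, hi, 256)
    best_t, best_var = candidates[0], -1.0
    for t in candidates[:-1]:
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            continue
        w0, w1 = below.size, above.size
        var = w0 * w1 * (below.mean() - above.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def point_in_polygon(x: float, y: float, vertices: np.ndarray) -> bool:
    """Ray casting with boundary-inclusive semantics (on-edge counts as inside)."""
    vertices = np.asarray(vertices, dtype=float)
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-segment check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 and \
                min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9:
            return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def rasterize_polygon_oracle(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            mask[r, c] = point_in_polygon(c, r, vertices)
    return mask


def kdtree_dilate(mask: np.ndarray, distance: float) -> np.ndarray:
    """Pixels within inclusive Euclidean distance of the foreground (KD-tree query)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or distance <= 0:
        return mask.copy()
    fg = np.argwhere(mask)
    all_px = np.argwhere(np.ones_like(mask))
    d, _ = cKDTree(fg).query(all_px)
    return (d <= distance).reshape(mask.shape)


def kdtree_erode(mask: np.ndarray, distance: float) -> np.ndarray:
    """Drop pixels within inclusive distance of background; image border is background."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or distance <= 0:
        return mask.copy()
    padded = np.pad(mask, 1, constant_values=False)
    bg = np.argwhere(~padded)
    all_px = np.argwhere(np.ones_like(padded))
    d, _ = cKDTree(bg).query(all_px)
    out = (d > distance).reshape(padded.shape)
    return out[1:-1, 1:-1]
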