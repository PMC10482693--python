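"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — per-pixel Python loops, BFS
labeling, exhaustive nearest-pixel scans — and shares no code with the
package's raster operators.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_focal_mean(values: np.ndarray, radius_m: float, pixel_size: float) -> np.ndarray:
    """Double-loop circular-kernel mean with edge shrink and NaN skipping."""
    n_rows, n_cols = values.shape
    k = int(radius_m // pixel_size)
    offsets = [
        (dy, dx)
        for dy in range(-k, k + 1)
        for dx in range(-k, k + 1)
        if (dy * pixel_size) ** 2 + (dx * pixel_size) ** 2 <= radius_m**2
    ]
    out = np.full(values.shape, np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            total = 0.0
            count = 0
            for dy, dx in offsets:
                rr, cc = r + dy, c + dx
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    v = values[rr, cc]
                    if not math.isnan(v):
                        total += v
                        count += 1
            if count:
                out[r, c] = total / count
    return out


def brute_force_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """BFS connected-component labeling of a boolean mask."""
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    n_rows, n_cols = mask.shape
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = [(r0, c0)]
                labels[r0, c0] = current
                while queue:
                    r, c = queue.pop()
                    for dy, dx in neigh:
                        rr, cc = r + dy, c + dx
                        if 0 <= rr < n_rows and 0 <= cc < n_cols and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels


def brute_force_proximity(mask: np.ndarray, max_distance_m: float, pixel_size: float) -> np.ndarray:
    """Exhaustive nearest-patch-pixel scan: 1 where center distance <= max."""
    src = np.argwhere(mask)
    out = np.zeros(mask.shape, dtype=np.uint8)
    if src.size == 0:
        return out
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            d2 = ((src[:, 0] - r) ** 2 + (src[:, 1] - c) ** 2).min() * pixel_size**2
            if math.sqrt(d2) <= max_distance_m:
                out[r, c] = 1
    return out


def brute_force_classify(
    veg_incl: np.ndarray,
    grass: np.ndarray,
    fsw: np.ndarray,
    building: np.ndarray,
    near_incl: np.ndarray,
    near_excl: np.ndarray,
    water_mask: np.ndarray,
    candidate_min: float = 0.005,
    urban_min: float = 0.15,
    intermix_veg_min: float = 0.5,
) -> np.ndarray:
    """Pure per-pixel rule-table reference classifier (Python loops)."""
    n_rows, n_cols = veg_incl.shape
    out = np.zeros((n_rows, n_cols), dtype=np.uint8)
    for r in range(n_rows):
        for c in range(n_cols):
            if water_mask[r, c]:
                out[r, c] = 255
                continue
            b = building[r, c]
            if not b > candidate_min:
                continue
            urban = b > urban_min
            if not urban and veg_incl[r, c] >= intermix_veg_min:
                out[r, c] = 1 if fsw[r, c] >= grass[r, c] else 2
            elif near_excl[r, c]:
                out[r, c] = 3
            elif near_incl[r, c]:
                out[r, c] = 4
    return out
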