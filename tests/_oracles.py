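"""Independent brute-force oracles used by the test suite.

Deliberately naive pure-Python implementations: exhaustive voxel scans,
breadth-first flood fill, and rank arithmetic.  They share no code with the
package so they can serve as a second route to the same answers.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: None,
    26: None,
}


def _offsets(connectivity: int):
    if connectivity == 6:
        return _OFFSETS[6]
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 18 and order == 3:
                    continue
                out.append((di, dj, dk))
    return out


def brute_force_segment(
    suv: np.ndarray,
    threshold_map: np.ndarray,
    exclusion: np.ndarray | None,
    connectivity: int,
    voxel_volume_ml: float,
    min_lesion_volume_ml: float = 0.0,
):
    """Exhaustive threshold scan + BFS flood fill.

    Returns a list of dicts (voxels frozenset, voxel_count, volume_ml,
    suv_mean, suv_max, centroid) sorted by descending volume then centroid.
    """
    shape = suv.shape
    candidate = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if suv[i, j, k] >= threshold_map[i, j, k]:
                    if exclusion is None or not exclusion[i, j, k]:
                        candidate[i, j, k] = True

    offsets = _offsets(connectivity)
    seen = np.zeros(shape, dtype=bool)
    lesions = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not candidate[i, j, k] or seen[i, j, k]:
                    continue
                queue = deque([(i, j, k)])
                seen[i, j, k] = True
                comp = []
                while queue:
                    ci, cj, ck = queue.popleft()
                    comp.append((ci, cj, ck))
                    for di, dj, dk in offsets:
                        ni, nj, nk = ci + di, cj + dj, ck + dk
                        if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                            if candidate[ni, nj, nk] and not seen[ni, nj, nk]:
                                seen[ni, nj, nk] = True
                                queue.append((ni, nj, nk))
                values = [float(suv[v]) for v in comp]
                volume = len(comp) * voxel_volume_ml
                if volume < min_lesion_volume_ml:
                    continue
                centroid = tuple(sum(c[a] for c in comp) / len(comp) for a in range(3))
                lesions.append(
                    {
                        "voxels": frozenset(comp),
                        "voxel_count": len(comp),
                        "volume_ml": volume,
                        "suv_mean": sum(values) / len(values),
                        "suv_max": max(values),
                        "centroid": centroid,
                    }
                )
    lesions.sort(key=lambda l: (-l["volume_ml"], l["centroid"]))
    return lesions


def spearman_by_ranks(x, y) -> float:
    """Pearson correlation of average ranks, spelled out."""

    def average_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1  # ranks are 1-based
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5


def reverse_km_median(times, events) -> float:
    """Product-limit median with the event indicator flipped, by hand."""
    pairs = sorted(zip(times, [not e for e in events]))
    n_at_risk = len(pairs)
    surv = 1.0
    idx = 0
    while idx < len(pairs):
        t = pairs[idx][0]
        d = sum(1 for tt, ee in pairs if tt == t and ee)
        c = sum(1 for tt, ee in pairs if tt == t and not ee)
        if d:
            surv *= 1 - d / n_at_risk
        if surv <= 0.5:
            return t
        n_at_risk -= d + c
        idx += sum(1 for tt, _ in pairs if tt == t)
    return float("inf")
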