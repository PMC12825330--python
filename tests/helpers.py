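"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code path with the
implementation it checks: per-voxel exhaustive nearest-nucleus search for
shell construction, and a hand-rolled BFS flood fill for connected-component
volumes.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_force_shells(labels: np.ndarray, radius: float) -> np.ndarray:
    """Exhaustive per-voxel shell assignment.

    For every background voxel, scan *all* nucleus voxels, find the minimal
    squared Euclidean distance (voxel units); if within radius, assign the
    smallest label id among the equally-nearest nuclei.
    """
    fg = np.argwhere(labels > 0)
    out = np.zeros_like(labels)
    if len(fg) == 0:
        return out
    fg_labels = labels[tuple(fg.T)]
    bg = np.argwhere(labels == 0)
    r2 = radius * radius
    chunk = 4096
    for start in range(0, len(bg), chunk):
        b = bg[start : start + chunk]
        d2 = ((b[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2)  # (nb, nf) int
        dmin = d2.min(axis=1)
        within = dmin <= r2
        for row in np.flatnonzero(within):
            cands = fg_labels[d2[row] == dmin[row]]
            out[tuple(b[row])] = cands.min()
    return out


def brute_force_overlaps(shells: np.ndarray, mask: np.ndarray) -> dict[int, tuple[int, int]]:
    """Per-shell (overlap_voxels, shell_voxels) by explicit voxel loops."""
    out: dict[int, tuple[int, int]] = {}
    for lid in np.unique(shells):
        if lid == 0:
            continue
        where = shells == lid
        out[int(lid)] = (int(np.sum(where & mask)), int(np.sum(where)))
    return out


def flood_fill_component_sizes(mask: np.ndarray) -> list[int]:
    """26-connected component sizes via BFS, independent of scipy/skimage."""
    visited = np.zeros(mask.shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    sizes = []
    for seed in map(tuple, np.argwhere(mask)):
        if visited[seed]:
            continue
        queue = deque([seed])
        visited[seed] = True
        size = 0
        while queue:
            v = queue.popleft()
            size += 1
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not visited[w]:
                        visited[w] = True
                        queue.append(w)
        sizes.append(size)
    return sizes


def random_label_volume(rng: np.random.Generator, shape=(32, 32, 32), n_blobs=8) -> np.ndarray:
    """Random instance volume: overlapping spheres rasterized first-come."""
    labels = np.zeros(shape, dtype=np.uint32)
    zz, yy, xx = np.indices(shape)
    for k in range(1, n_blobs + 1):
        c = rng.uniform(2, np.array(shape) - 2)
        r = rng.uniform(1.5, 4.0)
        inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r
        labels[inside & (labels == 0)] = k
    return labels
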