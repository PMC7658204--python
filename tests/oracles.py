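"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's FFT/ndimage code paths: dilation is
a literal union of translated structuring-element copies, components come
from a BFS flood fill, reconstruction from iterated conditional dilation,
and surface distances from all-pairs scans.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def shift_no_wrap(grid: np.ndarray, offset) -> np.ndarray:
    """Translate a boolean grid, filling exposed space with False."""
    out = np.zeros_like(grid)
    src, dst = [], []
    for o, n in zip(offset, grid.shape):
        o = int(o)
        if abs(o) >= n:
            return out
        if o >= 0:
            dst.append(slice(o, n))
            src.append(slice(0, n - o))
        else:
            dst.append(slice(0, n + o))
            src.append(slice(-o, n))
    out[tuple(dst)] = grid[tuple(src)]
    return out


def minkowski_dilate(grid: np.ndarray, se_grid: np.ndarray) -> np.ndarray:
    """Union of translates of the mask by every set SE offset."""
    center = np.array(se_grid.shape) // 2
    out = np.zeros_like(grid)
    for idx in np.argwhere(se_grid):
        out |= shift_no_wrap(grid, idx - center)
    return out


def duality_erode(grid: np.ndarray, se_grid: np.ndarray) -> np.ndarray:
    """Erosion as complement-of-dilation-of-complement.

    Out-of-bounds mask voxels count as foreground, realised by embedding
    the complement in a background-padded frame before dilating.
    """
    radii = [s // 2 for s in se_grid.shape]
    comp = np.pad(~grid, [(r, r) for r in radii], constant_values=False)
    dil = minkowski_dilate(comp, se_grid)
    crop = tuple(slice(r, r + n) for r, n in zip(radii, grid.shape))
    return ~dil[crop]


def brute_open(grid, se_grid):
    return minkowski_dilate(duality_erode(grid, se_grid), se_grid)


def brute_close(grid, se_grid):
    return duality_erode(minkowski_dilate(grid, se_grid), se_grid)


_NEIGHBORS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}
_NEIGHBORS[26] = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                  for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
_NEIGHBORS[18] = [n for n in _NEIGHBORS[26] if sum(map(abs, n)) <= 2]


def flood_fill_components(grid: np.ndarray, connectivity: int = 26):
    """BFS flood fill; returns a label grid (arbitrary ids) and sizes."""
    labels = np.zeros(grid.shape, dtype=np.int32)
    sizes = []
    nbrs = _NEIGHBORS[connectivity]
    next_id = 0
    for start in map(tuple, np.argwhere(grid)):
        if labels[start]:
            continue
        next_id += 1
        labels[start] = next_id
        queue = deque([start])
        size = 1
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in nbrs:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < grid.shape[0] and 0 <= p[1] < grid.shape[1]
                        and 0 <= p[2] < grid.shape[2]
                        and grid[p] and not labels[p]):
                    labels[p] = next_id
                    queue.append(p)
                    size += 1
        sizes.append(size)
    return labels, sizes


def geodesic_reconstruct(reference: np.ndarray, seeds: np.ndarray,
                         connectivity: int = 26) -> np.ndarray:
    """Iterated conditional dilation of the seeds inside the reference."""
    se = np.zeros((3, 3, 3), dtype=bool)
    for n in _NEIGHBORS[connectivity] + [(0, 0, 0)]:
        se[n[0] + 1, n[1] + 1, n[2] + 1] = True
    current = seeds & reference
    while True:
        grown = minkowski_dilate(current, se) & reference
        if np.array_equal(grown, current):
            return current
        current = grown


def brute_surface(grid: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent background (or border) voxel."""
    out = np.zeros_like(grid)
    for p in map(tuple, np.argwhere(grid)):
        for d in _NEIGHBORS[6]:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if not all(0 <= q[i] < grid.shape[i] for i in range(3)) \
                    or not grid[q]:
                out[p] = True
                break
    return out


def brute_surface_distances(a: np.ndarray, b: np.ndarray, spacing):
    """All-pairs MSSD and Hausdorff between two masks' surfaces, in mm."""
    spacing = np.asarray(spacing, dtype=float)
    pa = np.argwhere(brute_surface(a)) * spacing
    pb = np.argwhere(brute_surface(b)) * spacing
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    d_ab = dmat.min(axis=1)
    d_ba = dmat.min(axis=0)
    mssd = float(np.concatenate([d_ab, d_ba]).mean())
    hausdorff = float(max(d_ab.max(), d_ba.max()))
    return mssd, hausdorff


def random_mask(rng, shape, density=0.3) -> np.ndarray:
    return rng.random(shape) < density


def random_se(rng, max_extent=7, density=0.5) -> np.ndarray:
    shape = tuple(rng.choice(range(1, max_extent + 1, 2), size=3))
    grid = rng.random(shape) < density
    grid[tuple(s // 2 for s in shape)] |= bool(rng.integers(0, 2))
    if not grid.any():
        grid[tuple(s // 2 for s in shape)] = True
    return grid
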