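"""Pre/post-processing math for volumetric segmentation networks.

Anti-aliased resampling to a coarse isotropic grid, nearest-neighbour
label upsampling, a minimal overlapping tile cover for sliding-window
inference with overlap averaging, and the smooth IOU (soft Jaccard) loss.
None of this depends on any particular model.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .core import CTVolume, LabelMap

__all__ = ["smoothing_sigmas", "antialias_resample",
           "nearest_upsample_labels", "tile_cover", "pad_for_tiling",
           "average_overlaps", "iou_loss", "validate_probability_map",
           "DEFAULT_TILE_SHAPE"]


def validate_probability_map(probs: np.ndarray, atol: float = 1e-5) -> None:
    """Check a (3 spatial + classes) grid holds per-voxel distributions."""
    probs = np.asarray(probs)
    if probs.ndim != 4:
        raise ValueError("probability map must be 4-D (3 spatial + classes)")
    if probs.min() < -atol or probs.max() > 1 + atol:
        raise ValueError("probabilities must lie in [0, 1]")
    sums = probs.sum(axis=-1)
    if np.abs(sums - 1.0).max() > atol:
        raise ValueError("per-voxel probabilities must sum to 1")

DEFAULT_TILE_SHAPE = (120, 120, 160)

_GAUSS_TRUNCATE = 3.0  # kernel support in units of sigma


def smoothing_sigmas(target_mm: float, source_mm) -> tuple[float, ...]:
    """Per-axis anti-aliasing sigmas, in source-voxel units.

    sigma_k = (1/3) * max(r/u_k - 1, 0) for target resolution r and source
    spacing u: axes already at or below the target rate need no smoothing,
    coarser targets place the lowpass cutoff at the ratio of sampling
    rates.
    """
    if target_mm <= 0:
        raise ValueError(f"target resolution must be positive, got {target_mm}")
    return tuple((1.0 / 3.0) * max(target_mm / u - 1.0, 0.0)
                 for u in source_mm)


def antialias_resample(ct: CTVolume, target_mm: float = 3.0) -> CTVolume:
    """Resample to an isotropic grid with Gaussian anti-aliasing.

    Each axis is smoothed with its :func:`smoothing_sigmas` value, then
    linearly interpolated onto the target grid (voxel centres aligned).
    """
    sigmas = smoothing_sigmas(target_mm, ct.spacing)
    smoothed = ct.hu.astype(np.float64)
    if any(s > 0 for s in sigmas):
        smoothed = ndimage.gaussian_filter(smoothed, sigma=sigmas,
                                           truncate=_GAUSS_TRUNCATE)
    new_shape = tuple(max(1, round(n * u / target_mm))
                      for n, u in zip(ct.shape, ct.spacing))
    grids = [
        (np.arange(m) + 0.5) * (target_mm / u) - 0.5
        for m, u in zip(new_shape, ct.spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(smoothed, coords, order=1, mode="nearest")
    return CTVolume(out.astype(np.float32),
                    (target_mm, target_mm, target_mm))


def nearest_upsample_labels(labels: LabelMap, target_shape,
                            target_spacing) -> LabelMap:
    """Map label codes onto a new grid by nearest source voxel centre."""
    target_shape = tuple(int(n) for n in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    grids = [
        np.clip(np.round((np.arange(m) + 0.5) * (t / u) - 0.5), 0, n - 1
                ).astype(np.intp)
        for m, t, n, u in zip(target_shape, target_spacing,
                              labels.shape, labels.spacing)
    ]
    ix, iy, iz = np.meshgrid(*grids, indexing="ij")
    return LabelMap(labels.codes[ix, iy, iz], target_spacing)


def tile_cover(volume_shape, tile_shape=DEFAULT_TILE_SHAPE
               ) -> list[tuple[int, int, int]]:
    """Minimal set of tile offsets covering the volume.

    Per axis, ceil(extent/tile) tiles are spread evenly from offset 0 to
    extent - tile; overlap appears only when the extent is not an exact
    multiple of the tile.  Volumes smaller than one tile should be
    zero-padded before calling (see :func:`pad_for_tiling`).
    """
    volume_shape = tuple(int(n) for n in volume_shape)
    tile_shape = tuple(int(n) for n in tile_shape)
    for axis, (v, t) in enumerate(zip(volume_shape, tile_shape)):
        if v < t:
            raise ValueError(
                f"volume extent {v} smaller than tile extent {t} on axis "
                f"{axis}; zero-pad the volume first")
    per_axis = []
    for v, t in zip(volume_shape, tile_shape):
        n = math.ceil(v / t)
        if n == 1:
            per_axis.append([0])
        else:
            per_axis.append([int(round(i * (v - t) / (n - 1)))
                             for i in range(n)])
    return [(i, j, k) for i in per_axis[0] for j in per_axis[1]
            for k in per_axis[2]]


def pad_for_tiling(volume_shape, tile_shape=DEFAULT_TILE_SHAPE):
    """Symmetric zero-pad widths bringing each axis up to one tile."""
    pads = []
    for v, t in zip(volume_shape, tile_shape):
        short = max(t - v, 0)
        pads.append((short // 2, short - short // 2))
    return pads


def average_overlaps(tile_probs, volume_shape) -> np.ndarray:
    """Assemble tile probability maps into one volume, averaging overlaps.

    ``tile_probs`` is a list of ``(offset, probs)`` where ``probs`` has
    shape ``tile_shape + (C,)``.  Per voxel the unweighted mean over all
    covering tiles is taken, so per-voxel distributions stay normalised.
    """
    volume_shape = tuple(int(n) for n in volume_shape)
    first = np.asarray(tile_probs[0][1])
    n_classes = first.shape[-1]
    acc = np.zeros(volume_shape + (n_classes,), dtype=np.float64)
    cover = np.zeros(volume_shape, dtype=np.int64)
    for offset, probs in tile_probs:
        probs = np.asarray(probs)
        sl = tuple(slice(o, o + s) for o, s in zip(offset, probs.shape[:3]))
        acc[sl] += probs
        cover[sl] += 1
    if (cover == 0).any():
        raise RuntimeError("tile cover left voxels uncovered; offsets must "
                           "come from tile_cover()")
    return acc / cover[..., None]


def iou_loss(probs: np.ndarray, truth: LabelMap, classes) -> float:
    """Smooth IOU (soft Jaccard) loss, averaged over classes.

    For each class c with predicted probability map p and one-hot truth y:
    ``L_c = 1 - p.y / (||p||_1 + ||y||_1 - p.y)``.  The mean over all
    requested classes (background included) is returned.  On binary p this
    is exactly 1 minus the Jaccard index.  A class absent from both
    prediction and truth contributes 0 (perfect agreement).
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 4:
        raise ValueError("probability map must be 4-D (3 spatial + classes)")
    if probs.shape[:3] != truth.shape:
        raise ValueError(
            f"shape mismatch: {probs.shape[:3]} vs {truth.shape}")
    classes = list(classes)
    losses = []
    for idx, c in enumerate(classes):
        p = probs[..., idx]
        y = (truth.codes == c).astype(np.float64)
        dot = float((p * y).sum())
        denom = float(p.sum()) + float(y.sum()) - dot
        losses.append(0.0 if denom == 0 else 1.0 - dot / denom)
    return float(np.mean(losses))
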