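"""Segmentation evaluation: Dice, mean symmetric surface distance, Hausdorff.

Surface conventions (fixed here so numbers are reproducible): the surface
of a mask is the set of foreground voxels with at least one face-adjacent
background neighbour, the volume border counting as background.  Distances
are Euclidean between voxel centres in millimetres, using the per-axis
spacing.  MSSD pools the nearest-surface distances of both directions into
one mean; the Hausdorff distance is the true maximum over both directed
maxima (no percentile variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BinaryMask, LabelMap

__all__ = ["dice", "jaccard", "surface_mask", "surface_distances",
           "ClassMetrics", "MetricsReport", "evaluate_labelmaps"]


def _check_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    _check_same_shape(a, b)
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.grid & b.grid).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index (IOU) |A∩B| / |A∪B|; two empty masks score 1."""
    _check_same_shape(a, b)
    union = int((a.grid | b.grid).sum())
    if union == 0:
        return 1.0
    inter = int((a.grid & b.grid).sum())
    return inter / union


def surface_mask(mask: BinaryMask) -> BinaryMask:
    """Foreground voxels with a face-adjacent background neighbour.

    The volume border counts as background, so objects touching the border
    contribute surface there.
    """
    cross = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.grid, structure=cross,
                                      border_value=0)
    return BinaryMask(mask.grid & ~interior, mask.spacing)


def _surface_points_mm(mask: BinaryMask) -> np.ndarray:
    coords = np.argwhere(surface_mask(mask).grid)
    return coords * np.asarray(mask.spacing)


def surface_distances(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """(mean symmetric surface distance, Hausdorff distance), both in mm."""
    _check_same_shape(a, b)
    if a.spacing != b.spacing:
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not a.grid.any() or not b.grid.any():
        raise ValueError("surface distances are undefined for an empty mask")
    pa = _surface_points_mm(a)
    pb = _surface_points_mm(b)
    d_ab = cKDTree(pb).query(pa)[0]  # a-surface -> nearest b-surface
    d_ba = cKDTree(pa).query(pb)[0]
    mssd = float(np.concatenate([d_ab, d_ba]).mean())
    hausdorff = float(max(d_ab.max(), d_ba.max()))
    return mssd, hausdorff


@dataclass
class ClassMetrics:
    dice: float
    mssd: float | None       # None when either mask is empty
    hausdorff: float | None
    absent: bool = False     # class missing from both prediction and truth


@dataclass
class MetricsReport:
    """Per-class metrics over a prediction/truth label-map pair."""

    per_class: dict[int, ClassMetrics] = field(default_factory=dict)

    @property
    def mean_dice(self) -> float:
        return float(np.mean([m.dice for m in self.per_class.values()]))


def evaluate_labelmaps(pred: LabelMap, truth: LabelMap,
                       classes) -> MetricsReport:
    """One-vs-rest Dice/MSSD/Hausdorff for each requested class code."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    report = MetricsReport()
    for c in classes:
        mp = pred.mask(c)
        mt = truth.mask(c)
        d = dice(mp, mt)
        if mp.grid.any() and mt.grid.any():
            mssd, hd = surface_distances(mp, mt)
            report.per_class[c] = ClassMetrics(d, mssd, hd)
        else:
            absent = not mp.grid.any() and not mt.grid.any()
            report.per_class[c] = ClassMetrics(d, None, None, absent=absent)
    return report
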