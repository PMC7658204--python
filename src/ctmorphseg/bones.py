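"""Unsupervised morphological skeleton detection and segmentation.

Two intensity thresholds drive the algorithm: almost all bone tissue is
above ``tau1`` (0 HU) while the dense cortical exterior is above ``tau2``
(200 HU).

1. Threshold at ``tau2``: extracts cortical bone, plus unwanted
   hyper-intense tissue (aorta, kidneys, contrast-enhanced organs).
2. Keep only the largest connected component — the skeleton.  Hyper-intense
   tissue not attached to bone is discarded; so, as a known limitation,
   are ribs that never meet the spine inside a cropped scan.
3. Close with a 2.5 cm sphere to bridge gaps where cortical bone is too
   thin to resolve.
4. Intersect with ``hu > tau1`` to remove the soft tissue the closing
   swallowed between bones.
5. Fill per-axial-slice holes, recovering the low-density marrow at the
   centres of large bones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import BinaryMask, CTVolume, SegmentationError
from . import maskops, morphology

__all__ = ["BoneParams", "segment_bones"]

log = logging.getLogger(__name__)


@dataclass
class BoneParams:
    """Tunable parameters of the skeleton segmentation algorithm.

    tau1_hu: soft-tissue threshold (HU); step 4 keeps only voxels above it.
    tau2_hu: cortical-bone threshold (HU) for the initial detection.
    close_diameter_mm: diameter of the closing sphere bridging cortical gaps.
    connectivity: 3-D neighbourhood for component selection.
    """

    tau1_hu: float = 0.0
    tau2_hu: float = 200.0
    close_diameter_mm: float = 25.0
    connectivity: int = 26

    def __post_init__(self):
        if self.tau1_hu >= self.tau2_hu:
            raise ValueError("tau1_hu must be below tau2_hu")
        if self.close_diameter_mm <= 0:
            raise ValueError("close_diameter_mm must be positive")


def segment_bones(ct: CTVolume, params: BoneParams | None = None) -> BinaryMask:
    """Segment the skeleton of a CT volume; returns the final binary mask."""
    p = params or BoneParams()
    spacing = ct.spacing

    # 1. cortical-bone threshold (strict >)
    cortical = BinaryMask(ct.hu > p.tau2_hu, spacing)
    if not cortical.grid.any():
        raise SegmentationError(
            f"no bone-intensity voxels above {p.tau2_hu} HU", step=1)
    log.info("bones step 1 (threshold %.0f HU): %d voxels", p.tau2_hu,
             cortical.count())

    # 2. the largest component is the skeleton
    skeleton = maskops.largest_components(cortical, 1, p.connectivity)
    log.info("bones step 2 (largest component): %d voxels", skeleton.count())

    # 3. close to bridge thin/invisible cortical gaps
    sphere = morphology.make_sphere_se(p.close_diameter_mm, spacing)
    closed = morphology.close_mask(skeleton, sphere)
    log.info("bones step 3 (close, %.0f mm sphere): %d voxels",
             p.close_diameter_mm, closed.count())

    # 4. drop sub-tau1 tissue the closing captured between bones
    kept = BinaryMask(closed.grid & (ct.hu > p.tau1_hu), spacing)
    log.info("bones step 4 (threshold %.0f HU inside mask): %d voxels",
             p.tau1_hu, kept.count())

    # 5. fill axial holes: marrow centres of large bones
    filled = maskops.fill_holes_axial(kept)
    log.info("bones step 5 (fill axial holes): %d voxels", filled.count())
    return filled
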