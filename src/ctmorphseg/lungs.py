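"""Unsupervised morphological lung detection and segmentation.

The lungs are found as the two largest air pockets inside the body:

1. Threshold: keep voxels at or below ``tau_hu`` (default -150 HU), giving
   the air mask ``f_tau``.
2. Close with a thin rectangular prism along the anterior-posterior axis
   (1 x ceil(10 mm / d) x 1 voxels, d = y spacing) to puncture the exam
   table's thin wall, connecting its hollow interior to outside air.
3. Remove every component connected to the in-plane border of any axial
   slice (exterior air, punctured table interior).
4. Open with a 1 cm sphere to delete small air pockets and chest-wall gaps.
5. Keep the two largest components — almost certainly the lungs.
6. Reconstruct from ``f_tau``: return the full components of the air mask
   touched by the detected lungs, undoing the erosion of step 4.

The trachea is typically attached to the output; no attempt is made to
separate it.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

from .core import BinaryMask, CTVolume, ComponentCountError, SegmentationError
from . import maskops, morphology

__all__ = ["LungParams", "LungSegmentation", "segment_lungs",
           "segment_lungs_detailed"]

log = logging.getLogger(__name__)


@dataclass
class LungParams:
    """Tunable parameters of the lung segmentation algorithm.

    tau_hu: air threshold in HU; voxels <= tau_hu form the air mask.
    prism_mm: physical length of the table-puncturing closing prism (y axis).
    open_diameter_mm: diameter of the opening sphere that removes small
        air pockets.
    strict: if True, finding fewer than two candidate lungs is an error;
        otherwise the single component is returned with a warning.
    connectivity: 3-D neighbourhood for all component operations.
    """

    tau_hu: float = -150.0
    prism_mm: float = 10.0
    open_diameter_mm: float = 10.0
    strict: bool = False
    connectivity: int = 26

    def __post_init__(self):
        if self.prism_mm <= 0:
            raise ValueError("prism_mm must be positive")
        if self.open_diameter_mm <= 0:
            raise ValueError("open_diameter_mm must be positive")


@dataclass
class LungSegmentation:
    """Output mask plus the per-step intermediates for inspection."""

    mask: BinaryMask                 # final reconstructed lung mask
    air_mask: BinaryMask             # f_tau, step 1
    closed: BinaryMask               # step 2
    interior_air: BinaryMask         # step 3
    opened: BinaryMask               # step 4
    candidates: BinaryMask           # step 5
    n_candidates: int                # component count entering step 5
    warning: str | None = None


def _prism_extent_voxels(prism_mm: float, y_spacing_mm: float) -> int:
    n = math.ceil(prism_mm / y_spacing_mm)
    return n if n % 2 == 1 else n + 1


def segment_lungs_detailed(ct: CTVolume,
                           params: LungParams | None = None) -> LungSegmentation:
    """Run the six-step lung algorithm, keeping every intermediate mask."""
    p = params or LungParams()
    spacing = ct.spacing

    # 1. air mask: remove all voxels greater than tau
    f_tau = BinaryMask(ct.hu <= p.tau_hu, spacing)
    log.info("lungs step 1 (threshold %.0f HU): %d voxels", p.tau_hu,
             f_tau.count())

    # 2. puncture the exam-table wall with a thin prism along y
    extent = _prism_extent_voxels(p.prism_mm, spacing[1])
    prism = morphology.make_prism_se((1, extent, 1))
    closed = morphology.close_mask(f_tau, prism)
    log.info("lungs step 2 (close, 1x%dx1 prism): %d voxels", extent,
             closed.count())

    # 3. drop everything connected to an axial in-plane border
    interior = maskops.remove_boundary_connected(closed, p.connectivity)
    log.info("lungs step 3 (remove boundary-connected): %d voxels",
             interior.count())

    # 4. open with a sphere to remove small air pockets
    sphere = morphology.make_sphere_se(p.open_diameter_mm, spacing)
    opened = morphology.open_mask(interior, sphere)
    log.info("lungs step 4 (open, %.0f mm sphere): %d voxels",
             p.open_diameter_mm, opened.count())

    # 5. the two largest remaining components are the lungs
    labeling = maskops.label_components(opened, p.connectivity)
    n_found = labeling.n_components
    warning = None
    if n_found >= 2:
        candidates = maskops.largest_components(opened, 2, p.connectivity)
    elif n_found == 1 and not p.strict:
        warning = ("only one candidate air pocket found at step 5; "
                   "expected two lungs")
        warnings.warn(warning, stacklevel=3)
        candidates = maskops.largest_components(opened, 1, p.connectivity)
    else:
        raise ComponentCountError(
            f"lung segmentation step 5: found {n_found} candidate air "
            f"pockets, need 2", found=n_found, requested=2, step=5)
    log.info("lungs step 5 (keep 2 largest of %d): %d voxels", n_found,
             candidates.count())

    # 6. reconstruct the full air-mask components touched by the lungs
    seeds = candidates & f_tau
    mask = maskops.reconstruct_from_seeds(f_tau, seeds, p.connectivity)
    log.info("lungs step 6 (reconstruct): %d voxels", mask.count())

    return LungSegmentation(mask=mask, air_mask=f_tau, closed=closed,
                            interior_air=interior, opened=opened,
                            candidates=candidates, n_candidates=n_found,
                            warning=warning)


def segment_lungs(ct: CTVolume, params: LungParams | None = None) -> BinaryMask:
    """Segment the lungs of a CT volume; returns the final binary mask."""
    return segment_lungs_detailed(ct, params).mask
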