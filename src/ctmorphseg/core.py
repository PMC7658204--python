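"""Core in-memory containers for CT volumes, binary masks and label maps.

All grids are 3-D numpy arrays indexed ``(x, y, z)`` where, after canonical
reorientation, x runs left/right, y anterior/posterior and z
inferior/superior.  ``spacing`` is the physical voxel size in millimetres
along each axis.  A constant-z plane is an axial slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: CT-ORG organ label codes (stored on disk as 32-bit floats).
ORGAN_LABELS = {
    0: "background",
    1: "liver",
    2: "bladder",
    3: "lungs",
    4: "kidneys",
    5: "bone",
    6: "brain",
}

LABEL_BACKGROUND = 0
LABEL_LIVER = 1
LABEL_BLADDER = 2
LABEL_LUNGS = 3
LABEL_KIDNEYS = 4
LABEL_BONE = 5
LABEL_BRAIN = 6


class FormatError(ValueError):
    """A file's contents violate the expected label/volume conventions."""


class SegmentationError(RuntimeError):
    """A segmentation algorithm failed at a named step."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ComponentCountError(SegmentationError):
    """Fewer connected components were found than requested."""

    def __init__(self, message: str, found: int, requested: int,
                 step: int | None = None):
        super().__init__(message, step=step)
        self.found = found
        self.requested = requested


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing entries must be positive, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3-D scalar grid of Hounsfield units with per-axis voxel spacing."""

    hu: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.hu.ndim}-D")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("Hounsfield values must be finite")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape


@dataclass
class BinaryMask:
    """A 3-D boolean grid aligned to a :class:`CTVolume`."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.grid.ndim}-D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.grid.sum())

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.grid, self.spacing)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.grid & other.grid, self.spacing)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.grid | other.grid, self.spacing)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return (self.shape == other.shape
                and np.array_equal(self.grid, other.grid))


@dataclass
class StructuringElement:
    """A small binary kernel with its origin at the exact grid centre.

    Every axis length is odd so the origin voxel is unambiguous; the
    constructors promote even requests upward.
    """

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("structuring element must be 3-D")
        if any(s % 2 == 0 for s in self.grid.shape):
            raise ValueError(
                f"structuring element axes must be odd, got {self.grid.shape}")
        if not self.grid.any():
            raise ValueError("structuring element must have >= 1 voxel set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def origin(self) -> tuple[int, int, int]:
        return tuple(s // 2 for s in self.grid.shape)

    def reflected(self) -> "StructuringElement":
        """Point reflection through the origin."""
        return StructuringElement(self.grid[::-1, ::-1, ::-1])

    @property
    def is_symmetric(self) -> bool:
        return np.array_equal(self.grid, self.grid[::-1, ::-1, ::-1])


@dataclass
class LabelMap:
    """A 3-D integer grid in the CT-ORG organ coding (codes 0-6)."""

    codes: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3:
            raise ValueError("label map must be 3-D")
        if not np.issubdtype(self.codes.dtype, np.integer):
            rounded = np.rint(self.codes)
            if np.abs(self.codes - rounded).max(initial=0.0) > 1e-3:
                raise FormatError("label map contains non-integer values")
            self.codes = rounded
        self.codes = self.codes.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.codes), list(ORGAN_LABELS))
        if bad.size:
            raise FormatError(
                f"label codes outside the organ coding 0-6: {bad.tolist()}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.codes.shape

    def mask(self, code: int) -> BinaryMask:
        """One-vs-rest binarisation for one organ code."""
        return BinaryMask(self.codes == code, self.spacing)

    def present_codes(self) -> list[int]:
        return [int(c) for c in np.unique(self.codes)]
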