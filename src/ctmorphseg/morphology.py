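"""n-dimensional binary morphology computed by FFT convolution.

Dilation is evaluated as a real-valued convolution of the mask with the
structuring element followed by thresholding: a voxel is foreground iff the
convolution there is nonzero.  Because the ideal convolution of 0/1 inputs
is integer-valued, "nonzero" is tested as ``conv >= 0.5``, which is
maximally robust to FFT round-off.  Erosion is the binary dual,
``~dilate(~mask, se)``, with out-of-bounds voxels of the complement treated
as foreground — so erosion never eats inward from the volume border.
Opening and closing are the usual compositions.

A module-level switch selects the FFT back-end or a direct (spatial-domain)
back-end; the two agree voxel-exactly.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .core import BinaryMask, StructuringElement

__all__ = [
    "dilate", "erode", "open_mask", "close_mask",
    "make_sphere_se", "make_cube_se", "make_prism_se",
    "set_backend", "get_backend", "use_backend",
    "binary_convolution",
]

_BACKENDS = ("fft", "direct")
_backend = "fft"


def set_backend(name: str) -> None:
    """Select the morphology back-end: ``"fft"`` or ``"direct"``."""
    global _backend
    if name not in _BACKENDS:
        raise ValueError(f"unknown backend {name!r}; choose from {_BACKENDS}")
    _backend = name


def get_backend() -> str:
    return _backend


@contextlib.contextmanager
def use_backend(name: str):
    """Context manager that temporarily switches the morphology back-end."""
    previous = get_backend()
    set_backend(name)
    try:
        yield
    finally:
        set_backend(previous)


def _check_fits(mask: BinaryMask, se: StructuringElement) -> None:
    for axis, (m, s) in enumerate(zip(mask.shape, se.shape)):
        if s > m:
            raise ValueError(
                f"structuring element extent {s} exceeds mask extent {m} "
                f"along axis {axis}")


def binary_convolution(grid: np.ndarray, se: StructuringElement,
                       pad_value: int = 0) -> np.ndarray:
    """Real-valued convolution of a boolean grid with a structuring element.

    Out-of-bounds values are extrapolated with ``pad_value`` (0 for the mask
    itself, 1 for its complement).  The result is cropped so its shape
    matches ``grid``, centred on the structuring-element origin.
    """
    radii = [s // 2 for s in se.shape]
    padded = np.pad(grid.astype(np.float64),
                    [(r, r) for r in radii],
                    constant_values=float(pad_value))
    # 'valid' on the padded grid realises the centred crop exactly.
    return fftconvolve(padded, se.grid.astype(np.float64), mode="valid")


def _dilate_fft(grid: np.ndarray, se: StructuringElement) -> np.ndarray:
    return binary_convolution(grid, se, pad_value=0) >= 0.5


def _erode_fft(grid: np.ndarray, se: StructuringElement) -> np.ndarray:
    # out-of-bounds mask voxels count as foreground, so the complement is
    # extrapolated with 0: erosion never eats inward from the volume border
    return ~(binary_convolution(~grid, se, pad_value=0) >= 0.5)


def _dilate_direct(grid: np.ndarray, se: StructuringElement) -> np.ndarray:
    return ndimage.binary_dilation(grid, structure=se.grid, border_value=0)


def _erode_direct(grid: np.ndarray, se: StructuringElement) -> np.ndarray:
    # The duality definition erodes by the reflected kernel.
    return ndimage.binary_erosion(grid, structure=se.grid[::-1, ::-1, ::-1],
                                  border_value=1)


def dilate(mask: BinaryMask, se: StructuringElement,
           backend: str | None = None) -> BinaryMask:
    """Binary dilation (Minkowski sum with the structuring element)."""
    _check_fits(mask, se)
    backend = backend or _backend
    fn = _dilate_fft if backend == "fft" else _dilate_direct
    return BinaryMask(fn(mask.grid, se), mask.spacing)


def erode(mask: BinaryMask, se: StructuringElement,
          backend: str | None = None) -> BinaryMask:
    """Binary erosion, the complement dual of dilation.

    The complement is extrapolated with 1 outside the volume, so objects
    touching the volume border are not shrunk from that border.
    """
    _check_fits(mask, se)
    backend = backend or _backend
    fn = _erode_fft if backend == "fft" else _erode_direct
    return BinaryMask(fn(mask.grid, se), mask.spacing)


def open_mask(mask: BinaryMask, se: StructuringElement,
              backend: str | None = None) -> BinaryMask:
    """Morphological opening: erosion followed by dilation.

    Removes foreground features smaller than the structuring element.
    Idempotent for symmetric structuring elements (all constructors here
    produce symmetric ones).
    """
    return dilate(erode(mask, se, backend), se, backend)


def close_mask(mask: BinaryMask, se: StructuringElement,
               backend: str | None = None) -> BinaryMask:
    """Morphological closing: dilation followed by erosion.

    Fills background gaps smaller than the structuring element.
    """
    return erode(dilate(mask, se, backend), se, backend)


def _promote_odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def make_sphere_se(diameter_mm: float,
                   spacing: tuple[float, float, float]) -> StructuringElement:
    """Sphere of the given physical diameter, rasterised on the voxel grid.

    With anisotropic spacing the voxel-space shape is an ellipsoid: voxel
    offset ``v`` from the origin is set iff ``sum((v_k * u_k)**2) <= (d/2)**2``
    where ``u`` is the spacing in mm.  The grid is the smallest odd bounding
    box containing the ellipsoid.
    """
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    radius = diameter_mm / 2.0
    half = [int(math.floor(radius / u)) for u in spacing]
    axes = [np.arange(-h, h + 1) * u for h, u in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    grid = dx ** 2 + dy ** 2 + dz ** 2 <= radius ** 2
    return StructuringElement(grid)


def make_cube_se(extent: int = 3) -> StructuringElement:
    """Full cube of the given odd voxel extent (promoted to odd if even)."""
    n = _promote_odd(int(extent))
    if n < 1:
        raise ValueError("extent must be >= 1")
    return StructuringElement(np.ones((n, n, n), dtype=bool))


def make_prism_se(extent_voxels: tuple[int, int, int]) -> StructuringElement:
    """Solid rectangular prism with the given voxel extents.

    Each extent is promoted up to the nearest odd integer so the origin is
    a grid centre.
    """
    extents = tuple(int(e) for e in extent_voxels)
    if len(extents) != 3 or any(e < 1 for e in extents):
        raise ValueError(
            f"extents must be 3 positive integers, got {extent_voxels}")
    shape = tuple(_promote_odd(e) for e in extents)
    return StructuringElement(np.ones(shape, dtype=bool))
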