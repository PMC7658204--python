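"""NIfTI-1 reading/writing with the CT-ORG naming and label conventions.

Volumes are ``volume-<x>.nii.gz`` in Hounsfield units; label maps are
``labels-<x>.nii.gz`` with organs encoded as 32-bit floats (background 0,
liver 1, bladder 2, lungs 3, kidneys 4, bone 5, brain 6).  Files are
reoriented to the canonical RAS axis order on read, so the in-memory
grids always have x = left/right, y = anterior/posterior,
z = inferior/superior; spacing is taken from the header.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .core import CTVolume, FormatError, LabelMap, ORGAN_LABELS

__all__ = ["read_volume", "read_labels", "write_volume", "write_labels",
           "pair_paths"]

_LABEL_TOL = 1e-3


def _load_canonical(path):
    img = nib.load(os.fspath(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path) -> CTVolume:
    """Read a CT volume (HU) from a NIfTI-1 file."""
    data, spacing = _load_canonical(path)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {data.ndim}-D: {path}")
    return CTVolume(data, spacing)


def read_labels(path) -> LabelMap:
    """Read and validate an organ label map from a NIfTI-1 file.

    Values must be integers (within 1e-3, tolerating float storage) in the
    organ coding 0-6.
    """
    data, spacing = _load_canonical(path)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D label map, got {data.ndim}-D")
    rounded = np.rint(data)
    err = np.abs(data - rounded)
    if err.max(initial=0.0) > _LABEL_TOL:
        worst = float(data.ravel()[np.argmax(err)])
        raise FormatError(
            f"label map contains a non-integer value {worst!r} "
            f"(tolerance {_LABEL_TOL})")
    codes = rounded.astype(np.int16)
    bad = np.setdiff1d(np.unique(codes), list(ORGAN_LABELS))
    if bad.size:
        raise FormatError(
            f"label codes outside the organ coding 0-6: {bad.tolist()}")
    return LabelMap(codes, spacing)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(ct: CTVolume, path) -> None:
    """Write a CT volume as 32-bit float NIfTI-1."""
    img = nib.Nifti1Image(ct.hu.astype(np.float32), _affine(ct.spacing))
    img.header.set_zooms(ct.spacing)
    nib.save(img, os.fspath(path))


def write_labels(labels: LabelMap, path) -> None:
    """Write a label map as 32-bit float NIfTI-1 (CT-ORG storage)."""
    img = nib.Nifti1Image(labels.codes.astype(np.float32),
                          _affine(labels.spacing))
    img.header.set_zooms(labels.spacing)
    nib.save(img, os.fspath(path))


def pair_paths(case_number: int) -> tuple[str, str]:
    """Canonical (volume, labels) filename pair for a CT-ORG case number."""
    n = int(case_number)
    if n < 0:
        raise ValueError(f"case number must be >= 0, got {case_number}")
    return f"volume-{n}.nii.gz", f"labels-{n}.nii.gz"
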