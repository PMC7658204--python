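"""Seeded synthetic CT phantom with per-structure ground truth.

The phantom emulates the gross structure a thorax/abdomen CT presents to
threshold-and-morphology segmentation: air background; a hollow exam table
with a thin dense wall below the body (posterior along +y); an
elliptic-cylinder soft-tissue body; a skeleton (spine, sloping ribs,
pelvis) with a dense cortical shell around low-density marrow; two
air-filled lungs joined by a trachea exiting the top of the volume; soft
bladder/liver-like blobs; and configurable hyperintense decoy blobs
standing in for contrast-enhanced organs.  Additive Gaussian noise is
seeded and truncated so it can never carry a voxel across a segmentation
threshold.

Geometry scales with the physical extent of the requested grid; the
reference extent is 192 x 192 x 256 mm.  The ground-truth label map uses
the CT-ORG organ coding (lungs = 3, bone = 5; ancillary soft structures
stay background).  No anatomical realism is attempted — only the
topological and intensity relations the algorithms exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (CTVolume, LabelMap, LABEL_LUNGS, LABEL_BONE)

__all__ = ["TableSpec", "SkeletonSpec", "DecoySpec", "PhantomSpec",
           "Phantom", "render_phantom", "generate_phantom",
           "degrade_phantom", "DEGRADE_MODES"]

# reference physical extent (mm) the geometry constants below refer to
_REF_EXTENT = (192.0, 192.0, 256.0)

DEGRADE_MODES = ("crop_abdomen", "remove_table", "merge_lungs")

# thresholds the segmentation algorithms use; noise must never cross them
_THRESHOLDS = (-150.0, 0.0, 200.0)

# HU of the soft bladder/liver-like blobs (label 0; texture only)
_BLOB_HU = 30.0


@dataclass
class TableSpec:
    wall_hu: float = 100.0
    wall_thickness_mm: float = 2.0
    present: bool = True


@dataclass
class SkeletonSpec:
    cortical_hu: float = 700.0
    marrow_hu: float = 150.0
    shell_thickness_mm: float = 3.0


@dataclass
class DecoySpec:
    """A hyperintense soft-tissue blob disconnected from the skeleton."""
    hu: float = 250.0
    radius_mm: float = 12.0


def _default_decoys() -> list[DecoySpec]:
    return [DecoySpec(), DecoySpec()]


@dataclass
class PhantomSpec:
    """Parameter bundle describing a synthetic body."""

    shape: tuple[int, int, int] = (96, 96, 128)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_hu: float = 40.0
    lung_hu: float = -780.0
    air_hu: float = -1000.0
    table: TableSpec = field(default_factory=TableSpec)
    skeleton: SkeletonSpec = field(default_factory=SkeletonSpec)
    decoys: list[DecoySpec] = field(default_factory=_default_decoys)
    noise_sigma_hu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not (self.lung_hu < -150 < 0 < self.skeleton.marrow_hu < 200
                < self.skeleton.cortical_hu):
            raise ValueError(
                "HU defaults must satisfy lung < -150 < 0 < marrow < 200 "
                "< cortical")
        if not self.table.wall_thickness_mm < 10:
            raise ValueError("table wall must be thinner than 10 mm so the "
                             "lung algorithm's prism can puncture it")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        extent = self.extent_mm
        if any(e < m for e, m in zip(extent, (160.0, 160.0, 200.0))):
            raise ValueError(
                f"physical extent {extent} mm too small; structures need at "
                "least 160 x 160 x 200 mm")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def scales(self) -> tuple[float, float, float, float]:
        """(sx, sy, sz, s) relative to the reference extent; s = min."""
        sx, sy, sz = (e / r for e, r in zip(self.extent_mm, _REF_EXTENT))
        return sx, sy, sz, min(sx, sy, sz)


@dataclass
class Phantom:
    """A rendered phantom: volume, ground-truth labels and region masks.

    ``regions`` maps structure names (exterior_air, table_wall,
    table_interior, body, lungs, trachea, skeleton, ribs, marrow, decoys,
    blobs) to boolean masks in the volume grid.
    """

    ct: CTVolume
    labels: LabelMap
    regions: dict[str, np.ndarray]
    spec: PhantomSpec


# ---------------------------------------------------------------- geometry

def _coords(spec: PhantomSpec):
    """Open-grid physical coordinates (mm) of voxel centres."""
    axes = [(np.arange(n) + 0.5) * u
            for n, u in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def _sphere(coords, center, radius) -> np.ndarray:
    return _ellipsoid(coords, center, (radius, radius, radius))


def _elliptic_cylinder(coords, cx, cy, ax, ay, z0=None, z1=None) -> np.ndarray:
    x, y, z = coords
    inside = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    inside = inside & np.ones_like(z, dtype=bool)
    if z0 is not None:
        inside &= z >= z0
    if z1 is not None:
        inside &= z <= z1
    return inside


def _capsule(coords, p0, p1, radius) -> np.ndarray:
    """All voxels within ``radius`` of the segment p0-p1."""
    x, y, z = np.broadcast_arrays(*coords)
    p = np.stack([x, y, z], axis=-1).astype(np.float64)
    p0 = np.asarray(p0, dtype=np.float64)
    d = np.asarray(p1, dtype=np.float64) - p0
    t = np.clip(((p - p0) @ d) / (d @ d), 0.0, 1.0)
    closest = p0 + t[..., None] * d
    return ((p - closest) ** 2).sum(axis=-1) <= radius ** 2


def _box(coords, lo, hi) -> np.ndarray:
    x, y, z = coords
    return ((x >= lo[0]) & (x <= hi[0]) & (y >= lo[1]) & (y <= hi[1])
            & (z >= lo[2]) & (z <= hi[2]))


def _build_regions(spec: PhantomSpec) -> dict[str, np.ndarray]:
    sx, sy, sz, s = spec.scales
    X, Y, Z = spec.extent_mm
    c = _coords(spec)
    shell = spec.skeleton.shell_thickness_mm
    wt = spec.table.wall_thickness_mm

    regions: dict[str, np.ndarray] = {}

    # body: elliptic cylinder spanning all z
    body_cx, body_cy = 96 * sx, 88 * sy
    body_ax, body_ay = 70 * sx, 52 * sy
    body = _elliptic_cylinder(c, body_cx, body_cy, body_ax, body_ay)
    regions["body"] = body

    # exam table: hollow box below (posterior of) the body, open z ends
    if spec.table.present:
        lo = (26 * sx, 146 * sy, -1.0)
        hi = (166 * sx, 166 * sy, Z + 1.0)
        outer = _box(c, lo, hi)
        inner = _box(c, (lo[0] + wt, lo[1] + wt, -1.0),
                     (hi[0] - wt, hi[1] - wt, Z + 1.0))
        regions["table_wall"] = outer & ~inner
        regions["table_interior"] = inner
    else:
        regions["table_wall"] = np.zeros(spec.shape, dtype=bool)
        regions["table_interior"] = np.zeros(spec.shape, dtype=bool)

    # skeleton: spine + pelvis (cortical shell around marrow) + solid ribs
    spine_cx, spine_cy, spine_r = 96 * sx, 120 * sy, 14 * s
    spine = _elliptic_cylinder(c, spine_cx, spine_cy, spine_r, spine_r,
                               z0=8 * sz, z1=248 * sz)
    spine_marrow = _elliptic_cylinder(
        c, spine_cx, spine_cy, spine_r - shell, spine_r - shell,
        z0=8 * sz + shell, z1=248 * sz - shell)
    pelvis = _elliptic_cylinder(c, 96 * sx, 110 * sy, 50 * s, 30 * s,
                                z0=8 * sz, z1=40 * sz)
    pelvis_marrow = _elliptic_cylinder(
        c, 96 * sx, 110 * sy, 50 * s - shell, 30 * s - shell,
        z0=8 * sz + shell, z1=40 * sz - shell)
    ribs = np.zeros(spec.shape, dtype=bool)
    for z0 in (160 * sz, 200 * sz, 240 * sz):
        for side in (-1.0, 1.0):
            p0 = (96 * sx + side * 10 * s, 118 * sy, z0)
            p1 = (96 * sx + side * 46 * s, 95 * sy, z0 - 28 * sz)
            ribs |= _capsule(c, p0, p1, 4.5 * s)
    skeleton = spine | pelvis | ribs
    marrow = (spine_marrow | pelvis_marrow) & ~ribs
    regions["skeleton"] = skeleton
    regions["ribs"] = ribs
    regions["marrow"] = marrow
    regions["cortical"] = skeleton & ~marrow

    # lungs: two ellipsoids + trachea exiting the volume top + bronchi.
    # The body wall stays > 10 mm thick along y everywhere around the
    # lungs, so the table-puncturing closing cannot breach it.
    lung_centers = [(96 * sx - 34 * s, 88 * sy, 175 * sz),
                    (96 * sx + 34 * s, 88 * sy, 175 * sz)]
    lung_semi = (25 * s, 27 * s, 54 * sz)
    lungs = np.zeros(spec.shape, dtype=bool)
    for ctr in lung_centers:
        lungs |= _ellipsoid(c, ctr, lung_semi)
    trachea = _capsule(c, (96 * sx, 88 * sy, 215 * sz),
                       (96 * sx, 88 * sy, Z + 10.0), 4 * s)
    for ctr in lung_centers:
        trachea |= _capsule(c, (96 * sx, 88 * sy, 218 * sz),
                            (ctr[0], ctr[1], 180 * sz), 4 * s)
    regions["trachea"] = trachea & ~lungs
    regions["lungs"] = lungs | trachea

    # soft ancillary blobs (bladder- and liver-like; labelled background)
    blobs = _sphere(c, (96 * sx, 60 * sy, 26 * sz), 14 * s)
    blobs |= _sphere(c, (96 * sx - 38 * s, 85 * sy, 112 * sz), 20 * s)
    regions["blobs"] = blobs

    # hyperintense decoys, cycled over fixed anchor positions
    anchors = [(96 * sx - 36 * s, 70 * sy, 80 * sz),
               (96 * sx + 36 * s, 70 * sy, 95 * sz),
               (96 * sx - 30 * s, 60 * sy, 60 * sz),
               (96 * sx + 30 * s, 60 * sy, 110 * sz)]
    decoy_masks = [_sphere(c, anchors[i % len(anchors)], d.radius_mm * s)
                   for i, d in enumerate(spec.decoys)]
    regions["decoy_list"] = decoy_masks
    regions["decoys"] = (np.logical_or.reduce(decoy_masks) if decoy_masks
                         else np.zeros(spec.shape, dtype=bool))

    outside = ~(body | regions["table_wall"])
    regions["exterior_air"] = outside & ~regions["table_interior"]
    return regions


def _validate_regions(regions: dict[str, np.ndarray]) -> None:
    conflicts = []
    if (regions["table_wall"] & regions["body"]).any():
        conflicts.append("exam table intersects the body")
    if (regions["decoys"] & (regions["skeleton"] | regions["lungs"])).any():
        conflicts.append("a decoy blob touches the skeleton or lungs")
    if (regions["lungs"] & ~regions["body"]).any():
        conflicts.append("lungs extend outside the body")
    if (regions["skeleton"] & ~regions["body"]).any():
        conflicts.append("skeleton extends outside the body")
    if conflicts:
        raise ValueError("inconsistent phantom geometry: "
                         + "; ".join(conflicts))


def _noise_cap(spec: PhantomSpec) -> float:
    """Largest |noise| that keeps every structure on its threshold side.

    Capped at 40% of the smallest HU margin between any rendered intensity
    and any segmentation threshold.
    """
    hus = [spec.air_hu, spec.lung_hu, spec.body_hu,
           spec.skeleton.cortical_hu, spec.skeleton.marrow_hu]
    if spec.table.present:
        hus.append(spec.table.wall_hu)
    hus += [d.hu for d in spec.decoys]
    hus.append(_BLOB_HU)
    margin = min(abs(h - t) for h in hus for t in _THRESHOLDS)
    return 0.4 * margin


def render_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Render a phantom, keeping the per-structure region bookkeeping."""
    spec = spec or PhantomSpec()
    regions = _build_regions(spec)
    _validate_regions(regions)

    hu = np.full(spec.shape, spec.air_hu, dtype=np.float32)
    labels = np.zeros(spec.shape, dtype=np.int16)

    # overwrite order: later structures carve into earlier ones
    hu[regions["table_wall"]] = spec.table.wall_hu
    hu[regions["table_interior"]] = spec.air_hu
    hu[regions["body"]] = spec.body_hu
    hu[regions["blobs"] & regions["body"]] = _BLOB_HU
    for decoy_spec, decoy_mask in zip(spec.decoys, regions["decoy_list"]):
        hu[decoy_mask] = decoy_spec.hu
    hu[regions["lungs"]] = spec.lung_hu
    hu[regions["cortical"]] = spec.skeleton.cortical_hu
    hu[regions["marrow"]] = spec.skeleton.marrow_hu

    # labels follow the same overwrite order
    lungs_final = regions["lungs"] & ~regions["skeleton"]
    labels[lungs_final] = LABEL_LUNGS
    labels[regions["skeleton"]] = LABEL_BONE
    regions = dict(regions)
    regions["lungs"] = lungs_final

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        cap = _noise_cap(spec)
        noise = rng.normal(0.0, spec.noise_sigma_hu, size=spec.shape)
        hu += np.clip(noise, -cap, cap).astype(np.float32)

    ct = CTVolume(hu, spec.spacing)
    return Phantom(ct, LabelMap(labels, spec.spacing), regions, spec)


def generate_phantom(spec: PhantomSpec | None = None
                     ) -> tuple[CTVolume, LabelMap]:
    """Render a phantom; returns (volume, ground-truth label map)."""
    ph = render_phantom(spec)
    return ph.ct, ph.labels


def degrade_phantom(ct: CTVolume, mode: str,
                    spec: PhantomSpec | None = None) -> CTVolume:
    """Produce an adversarial variant that triggers a known failure mode.

    crop_abdomen: cut the scan below the rib-spine junctions, so the kept
        rib fragments are disconnected from the spine (and dropped by the
        skeleton algorithm's largest-component step).
    remove_table: replace the exam table with air; lung segmentation
        should be unaffected.
    merge_lungs: bridge the two lungs with a wide air channel that
        survives the 1 cm opening, so only one candidate remains.
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(f"unknown degrade mode {mode!r}; "
                         f"choose from {DEGRADE_MODES}")
    if spec is None:
        spec = PhantomSpec(shape=ct.shape, spacing=ct.spacing,
                           noise_sigma_hu=0.0)
    sx, sy, sz, s = spec.scales

    if mode == "crop_abdomen":
        z_cut_mm = 150 * sz
        n_keep = max(1, int(z_cut_mm / ct.spacing[2]))
        return CTVolume(ct.hu[:, :, :n_keep].copy(), ct.spacing)

    hu = ct.hu.copy()
    if mode == "remove_table":
        regions = _build_regions(spec)
        table = regions["table_wall"] | regions["table_interior"]
        hu[table] = spec.air_hu
        return CTVolume(hu, ct.spacing)

    # merge_lungs: wide air channel between the two lung centres
    c = _coords(spec)
    channel = _capsule(c, (96 * sx - 34 * s, 88 * sy, 175 * sz),
                       (96 * sx + 34 * s, 88 * sy, 175 * sz), 12 * s)
    hu[channel] = spec.lung_hu
    return CTVolume(hu, ct.spacing)
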