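# Methods

## Binary morphology by FFT convolution

All four basic operators act on 3-D boolean masks with a small binary
structuring element (SE) whose origin is the exact grid centre. Dilation
is a real-valued convolution of the mask with the SE followed by
thresholding. The ideal convolution of 0/1 inputs is integer-valued, so
the "nonzero" test is implemented as `conv >= 0.5` — the midpoint between
0 and 1 is maximally robust to FFT round-off (observed round-off is
below 1e-3 on all tested sizes, and the suite asserts it never flips a
voxel). The convolution is zero-padded to full size and cropped centred
on the SE origin so the output shape equals the input shape.

Conventions, fixed once:

- **Odd SE extents.** Every axis of an SE is odd; even requests are
  promoted upward. This removes all phase ambiguity in the centred crop.
- **Border handling.** Dilation extrapolates out-of-bounds voxels with
  background. Erosion is the dual `¬dilate(¬f, se)` with out-of-bounds
  *mask* voxels counted as foreground, so erosion never shrinks an object
  inward from the volume border (an all-true volume erodes to itself).
  The alternative convention (background outside) would erode every
  border-touching structure by half the SE per closing, biasing the
  segmentations at scan edges.
- **Physical-unit spheres.** A sphere of diameter `d` mm rasterises as a
  voxel ellipsoid: offset `v` is set iff `Σ (v_k u_k)² ≤ (d/2)²` with
  `u` the per-axis spacing. Anisotropic voxels therefore get anisotropic
  voxel counts, which keeps the operation's physical scale correct.
- **Back-ends.** The FFT back-end (scipy `fftconvolve`) and a direct
  spatial back-end (scipy.ndimage binary morphology, with the SE
  reflected for erosion so both realise the same dual) must agree
  bit-exactly; this is an asserted test surface, not an approximation.

Opening/closing are the compositions; their idempotence holds for
symmetric SEs, and every SE constructor in the package produces symmetric
grids.

## Connected components

3-D connectivity defaults to 26 (diagonal contact counts), which keeps
thin diagonal connections — e.g. a lung's apex — in one component.
Per-slice hole filling uses 4-connected background so a diagonal leak
does not empty a hole. Component ids are deterministic: sorted by size
descending, ties broken by smallest linear voxel index. "Connected to the
boundary of any axial slice" means the in-plane (x/y) frame of each
constant-z slice; the first and last z slices do not count, so structures
cut by the scan's z extent (trachea at the top of a thorax scan) survive
while exterior air and the punctured table interior are removed.
Morphological reconstruction from seeds returns exactly the components of
the reference mask that intersect the seeds — the fixpoint of conditional
dilation, computed via labeling rather than iteration.

## Lung segmentation

Six steps (defaults in parentheses): threshold `hu ≤ τ` (τ = −150 HU,
inclusive at equality); close with a `1 × ⌈p/d⌉ × 1` voxel prism
(p = 10 mm, d = anterior–posterior spacing, extent promoted to odd) to
puncture the exam table's thin wall; remove axial-border-connected
components; open with a sphere (10 mm diameter); keep the two largest
components; reconstruct from the thresholded air mask, seeding with the
intersection of the step-5 mask and the air mask (opening can move the
mask off the air voxels; the intersection guarantees valid seeds). The
trachea remains attached to the output by design. If fewer than two
candidates survive step 5, strict mode raises an error naming the step;
otherwise the single component is returned with a warning. The prism's
long axis runs anterior–posterior (supine patient, table wall below), and
its length uses the y-axis spacing.

## Skeleton segmentation

Five steps: threshold `hu > τ₂` (200 HU, strict) for cortical bone; keep
the largest component; close with a sphere (25 mm diameter); intersect
with `hu > τ₁` (0 HU, strict) — the threshold acts on the closed mask,
since its purpose is to discard the soft tissue the closing swallowed;
fill per-axial-slice holes, which recovers marrow centres of large bones
(including cavities wider than the closing sphere, e.g. the pelvis).
Known limitations are reproduced, not patched: ribs disconnected from the
spine in cropped scans are dropped at step 2, and soft tissue above 0 HU
in concavities near bone junctions is retained, so the algorithm
over-segments slightly (Dice ≈ 0.93 on the phantom).

## Evaluation metrics

The surface of a mask is its set of foreground voxels with at least one
face-adjacent background neighbour, the volume border counting as
background. Distances are Euclidean between voxel centres in mm. MSSD
pools the nearest-surface distances of both directions into a single
mean; Hausdorff is the true maximum of both directed maxima (no
percentile variant). These conventions are fixed and documented because
published surface-distance numbers are not comparable without them. Empty
masks: Dice of two empty masks is 1; surface distances on an empty mask
are an error, and the label-map report flags such classes as absent
instead of failing.

## Network support math

- Anti-aliased resampling to resolution `r` (default 3 mm) smooths each
  axis with `σ_k = (1/3)·max(r/u_k − 1, 0)` in source-voxel units
  (Gaussian truncated at 3σ), then interpolates trilinearly; axes already
  at or above the target resolution get σ = 0. Label maps upsample by
  nearest source voxel centre, which cannot invent new codes.
- The tile cover uses `ceil(extent/tile)` tiles per axis (minimal),
  offsets spread evenly from 0 to `extent − tile`; overlap predictions
  are averaged unweighted, which preserves per-voxel normalisation.
  Volumes smaller than one tile are zero-padded symmetrically first.
- The smooth IOU loss is averaged over all requested classes including
  background; a class absent from both prediction and truth contributes
  0 (perfect-agreement convention), keeping batch evaluation total.

## The synthetic phantom

The phantom emulates exactly the structure the two algorithms exploit,
not anatomy: an air background (−1000 HU); a hollow exam table with a
2 mm, 100 HU wall below the body; an elliptic-cylinder body (40 HU); a
skeleton — spine, three rib pairs sloping inferolaterally, pelvis — with
a 700 HU cortical shell (3 mm) around 150 HU marrow; two lung ellipsoids
(−780 HU) joined by an 8 mm trachea exiting the top slice; soft
bladder/liver-like blobs (30 HU, labelled background); and hyperintense
decoy blobs (250 HU) disconnected from the skeleton, standing in for
contrast-enhanced organs. Geometry scales with the physical extent
(reference 192 × 192 × 256 mm); the default grid is 96 × 96 × 128 at
2 mm isotropic, a size at which every pipeline stage runs in well under a
second. The body wall is kept thicker than 10 mm along y everywhere
around the lungs so the table-puncturing closing cannot breach it, while
the table wall (< 10 mm) is always punctured.

Noise is seeded Gaussian (default σ = 10 HU) clipped to 40% of the
smallest margin between any rendered intensity and any threshold
(−150, 0, 200 HU), so noise can never flip a voxel's threshold side —
segmentation on the phantom is therefore exactly reproducible, and the
lung recovery is exact (Dice 1.0). What passing on the phantom does
*not* show: robustness to partial-volume voxels straddling thresholds,
streak/beam-hardening artifacts, pathology (consolidated lungs,
osteolytic bone), or non-axis-aligned patient orientation beyond the
canonical reorientation on file read. Those require real scans.

Degraded variants reproduce the known failure modes: `crop_abdomen` cuts
the scan below the rib–spine junctions (detached rib fragments are then
dropped by the largest-component step); `merge_lungs` bridges the lungs
with a 24 mm air channel that survives the 1 cm opening, collapsing
step 5 to a single candidate; `remove_table` deletes the table, which
must leave lung output essentially unchanged.

## File conventions

Volumes and label maps are NIfTI-1; organ labels are stored as 32-bit
floats with codes background 0, liver 1, bladder 2, lungs 3, kidneys 4,
bone 5, brain 6, and filenames `volume-<x>.nii.gz` / `labels-<x>.nii.gz`.
On read, files are reoriented to canonical axes (x left/right,
y anterior/posterior, z inferior/superior) and label floats are rounded
with a 1e-3 tolerance and validated against the coding; out-of-range or
non-integer values are format errors.

## Problem sizes

The test suite and the acceptance script use the default phantom
(96 × 96 × 128 voxels at 2 mm), 10 phantom seeds per recovery check, 200
random instances for morphology-oracle equivalence (masks up to 32³, SEs
up to 9³), and brute-force O(n²) distance oracles on 7³ masks. These
sizes give exhaustive bit-level checks for the morphology and
comfortable statistical coverage for the pipelines while keeping a full
run in tens of seconds.
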