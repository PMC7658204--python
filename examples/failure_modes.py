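"""Reproduce the documented failure modes of the morphological algorithms.

Threshold-and-morphology segmentation fails catastrophically when its
structural assumptions break: ribs disconnected from the spine are
dropped, and lungs bridged by an air channel collapse into one candidate.
"""

import ctmorphseg as cm

ph = cm.render_phantom(cm.PhantomSpec(seed=7))

# 1. abdominal crop: the scan ends below the rib-spine junctions
cropped = cm.degrade_phantom(ph.ct, "crop_abdomen")
out = cm.segment_bones(cropped)
ribs = ph.regions["ribs"][:, :, :cropped.shape[2]]
print(f"cropped scan: {ribs.sum()} rib voxels present, "
      f"{(out.grid & ribs).sum()} segmented")
# The detached fragments lose to the spine at the largest-component step.

# 2. merged lungs: a wide air bridge survives the 1 cm opening
merged = cm.degrade_phantom(ph.ct, "merge_lungs")
try:
    cm.segment_lungs(merged, cm.LungParams(strict=True))
except cm.ComponentCountError as exc:
    print(f"merged lungs (strict): {exc}")

# 3. removing the exam table is a no-op for lung segmentation
no_table = cm.degrade_phantom(ph.ct, "remove_table")
base = cm.segment_lungs(ph.ct)
other = cm.segment_lungs(no_table)
print(f"lung mask voxels changed by table removal: "
      f"{(base.grid ^ other.grid).sum()}")
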