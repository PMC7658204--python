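"""Network pre/post-processing math: resampling, tiling, smooth IOU loss.

Shows the anti-aliased resampling to 3 mm, the overlapping tile cover used
for sliding-window inference, and the smooth IOU (soft Jaccard) training
loss evaluated on a deliberately imperfect prediction.
"""

import numpy as np

import ctmorphseg as cm

ph = cm.render_phantom(cm.PhantomSpec(seed=7))

print("anti-aliasing sigmas at 2 mm source spacing:",
      cm.smoothing_sigmas(3.0, ph.ct.spacing))
coarse = cm.antialias_resample(ph.ct, target_mm=3.0)
print(f"resampled {ph.ct.shape} @ {ph.ct.spacing} mm -> "
      f"{coarse.shape} @ {coarse.spacing} mm")

pads = cm.pad_for_tiling(coarse.shape)
padded_shape = tuple(n + lo + hi for n, (lo, hi) in zip(coarse.shape, pads))
offsets = cm.tile_cover(padded_shape)
print(f"tile cover of padded shape {padded_shape}: {len(offsets)} tiles")

# smooth IOU loss: perfect one-hot prediction scores 0; dilating the lung
# mask by one voxel leaves a small positive loss
classes = [0, 3, 5]
truth = ph.labels
perfect = np.stack([(truth.codes == c).astype(float) for c in classes], -1)
print(f"loss at one-hot agreement: {cm.iou_loss(perfect, truth, classes):.4f}")

blurred = cm.dilate(truth.mask(3), cm.make_cube_se(3))
pred_codes = truth.codes.copy()
pred_codes[blurred.grid] = 3
pred = np.stack([(pred_codes == c).astype(float) for c in classes], -1)
print(f"loss with lungs dilated by one voxel: "
      f"{cm.iou_loss(pred, truth, classes):.4f}")
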