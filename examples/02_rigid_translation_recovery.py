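"""Bone-driven translation registration on the synthetic head phantom.

Applies a known sub-voxel translation to the phantom and recovers it by
maximising the Pearson correlation of the bone-thresholded images.
"""

import numpy as np

from shrinkreg import make_head_phantom, register_translation, translate_phantom

ph = make_head_phantom()
t_true = np.array([2.5, -4.2, 6.8])  # (z, y, x) mm, includes sub-voxel parts
moving = translate_phantom(ph.image, t_true)

t_rec = register_translation(ph.image, moving)
residual = np.linalg.norm(t_rec - t_true)

print("applied translation  (z, y, x) mm:", t_true)
print("recovered translation (z, y, x) mm:", np.round(t_rec, 3))
print(f"residual: {residual:.3f} mm (the voxel size is 2-3 mm)")
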