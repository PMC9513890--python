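"""VOI geometry and the DSC / Hausdorff / volumetric-similarity metrics.

Crops a label-centred cube, pastes a prediction back into the full volume,
and scores a deliberately imperfect prediction against ground truth.
"""

import numpy as np

from aneuseg import desk_spec, generate_phantom
from aneuseg.metrics import score_pair
from aneuseg.voi import crop_cube, label_centroid, paste_back

s = generate_phantom(desk_spec(seed=12))
label = s.bundle.label

center = label_centroid(label)
crop, box = crop_cube(label, center, 32)
print(f"label centroid {center}; crop shape {crop.shape}; "
      f"box bounds {box.lo} .. {box.hi}, padding {box.pad_before}/{box.pad_after}")

restored = paste_back([(crop, box)], label.shape, label.spacing)
print(f"crop+paste recovers {int((restored.data & label.data).sum())} of "
      f"{int(label.data.sum())} label voxels")

# an imperfect prediction: the ground truth shifted by 2 voxels
pred = label.with_data(np.roll(label.data, 2, axis=0))
scores = score_pair(label, pred, label.spacing)
print(f"\nshifted-prediction scores: DSC {scores.dsc:.3f}, "
      f"HD {scores.hd_mm:.2f} mm, VS {scores.vs:.3f}")
print("DSC penalizes the lost overlap, HD measures the worst contour "
      "mismatch in mm, VS stays 1.0 because the volumes are equal.")
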