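"""Residual detection maps: localise what the model flagged.

Uses an untrained-but-plausible setup kept tiny for speed: trains briefly,
reconstructs one lesion-bearing slice, binarises the emphysema-direction
residual inside the lungs and writes a PNG overlay with the candidate
regions tinted green.
"""

import numpy as np

from minipae import (
    ModelConfig,
    PhantomSpec,
    build_model,
    candidate_regions,
    generate_cohort,
    generate_phantom,
    overlay,
    segment_lungs,
    train,
)
from minipae.anomaly_model import _erode2d
from minipae.detection import save_overlay
from minipae.pipeline import _participant_slices

train_cohort = generate_cohort(8, 0, seed=2)
x_tr = np.concatenate(
    [
        _participant_slices(v, segment_lungs(v).mask, 11, 6)[0]
        for v, _ in train_cohort
    ]
)
cfg = ModelConfig(epochs=8, seed=0)
model = train(build_model(cfg), x_tr, config=cfg)

vol, truth = generate_phantom(PhantomSpec(lesion_count=3, seed=41))
lung = segment_lungs(vol).mask
slices, masks, idx = _participant_slices(vol, lung, 11, 6)
lesion_areas = [truth.lesion_mask[i].sum() for i in idx]
j = int(np.argmax(lesion_areas))

x = slices[j]
xp = model.reconstruct(x[None, None].astype(np.float32))[0, 0]
residual = np.clip(xp - x, 0, None)  # emphysema-direction residual
det = candidate_regions(residual, _erode2d(masks[j]), threshold=0.5)
hit = (det.candidate_mask & truth.lesion_mask[idx[j]]).sum()
print(f"slice {idx[j]}: {det.candidate_mask.sum()} candidate pixels, "
      f"{hit} overlap the true lesion ({truth.lesion_mask[idx[j]].sum()} lesion px)")

save_overlay(det, x, "scratch/detection_overlay.png")
print("overlay written to scratch/detection_overlay.png "
      "(candidate regions tinted green on the input slice)")
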