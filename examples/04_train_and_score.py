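"""Train the adversarial auto-encoder on normal slices and score a mix.

A deliberately small run (12 normal training phantoms, 10 epochs): trains
on minIP-11 slices from normals only, calibrates the scorer, then scores
slices from 3 held-out normal and 3 emphysema phantoms. Prints per-
participant mean and max slice scores; emphysema participants should
surface at the top. Takes a couple of minutes on a laptop CPU.
"""

import numpy as np

from minipae import ModelConfig, build_model, generate_cohort, segment_lungs, train
from minipae.anomaly_model import calibrate_scores, raw_anomaly_scores
from minipae.pipeline import _participant_slices

train_cohort = generate_cohort(12, 0, seed=1)
test_cohort = generate_cohort(3, 3, seed=900)

x_tr, m_tr = [], []
for vol, _ in train_cohort:
    sl, mk, _ = _participant_slices(vol, segment_lungs(vol).mask, 11, 8)
    x_tr.append(sl)
    m_tr.append(mk)
x_tr, m_tr = np.concatenate(x_tr), np.concatenate(m_tr)

cfg = ModelConfig(epochs=10, seed=0)
model = build_model(cfg)
train(model, x_tr, config=cfg)
calibrate_scores(model, x_tr, m_tr)
print(f"trained {cfg.epochs} epochs; final reconstruction (L1) loss "
      f"{model.history['contextual'][-1]:.3f}\n")

print(f"{'participant':>12} {'label':>10} {'mean score':>11} {'max score':>10}")
for vol, truth in test_cohort:
    sl, mk, _ = _participant_slices(vol, segment_lungs(vol).mask, 11, 8)
    raws, _ = raw_anomaly_scores(model, sl, lung_masks=mk)
    print(f"{vol.participant_id:>12} {truth.label:>10} {raws.mean():11.2f} {raws.max():10.2f}")
print("\nRaw scores are standardised against the normal calibration set:")
print("values near 0 are typical of healthy lungs, large positives are anomalies.")
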