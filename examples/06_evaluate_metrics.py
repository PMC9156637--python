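"""Evaluation statistics on a worked screening result.

Recomputes the headline metrics of a balanced 40/40 screening cohort from
its confusion counts, runs a seeded bootstrap CI on simulated participant
scores, compares two classifiers with McNemar's test, and measures
agreement between two categorisations with Cohen's kappa.
"""

import numpy as np

from minipae import (
    ConfusionCounts,
    bootstrap_auc_ci,
    cohens_kappa,
    mcnemar_test,
    metrics_from_counts,
    roc_auc,
)

# balanced cohort, 5 false negatives and 7 false positives out of 40/40
m = metrics_from_counts(ConfusionCounts(tp=35, fn=5, fp=7, tn=33))
print(f"sensitivity {m['sensitivity']:.2f}, specificity {m['specificity']:.2f}, "
      f"F1 {m['f1']:.2f}")

rng = np.random.default_rng(0)
labels = np.r_[np.ones(40, int), np.zeros(40, int)]
scores = np.r_[rng.normal(0.65, 0.15, 40), rng.normal(0.35, 0.15, 40)]
auc = roc_auc(labels, scores)
lo, hi = bootstrap_auc_ci(labels, scores, n_iter=1000, seed=13)
print(f"AUC {auc:.3f} (95% bootstrap CI {lo:.3f}-{hi:.3f}, 1000 resamples)")

correct_a = rng.random(80) > 0.15  # classifier A right 85% of the time
correct_b = correct_a.copy()
flip = rng.random(80) < 0.10  # B disagrees on ~10% of participants
correct_b[flip] = ~correct_b[flip]
stat, p = mcnemar_test(correct_a, correct_b)
print(f"McNemar A vs B: p = {p:.4f} "
      "(small p would mean the two settings err on different participants)")

cat_a = (scores > 0.5).astype(int)
cat_b = labels
print(f"kappa between threshold categorisation and truth: "
      f"{cohens_kappa(cat_a, cat_b):.3f}")
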