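"""Per-participant slice sampling and the participant-level decision rule.

A scan is represented by n axial slices sampled evenly over the height of
the lungs. The participant rule is conservative, as befits screening: a
participant is negative only if every sampled slice is classified
non-emphysema; a single positive slice makes the participant positive.
Equivalently, the participant score is the maximum slice score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default number of slices per participant at test scale
DEFAULT_N_SLICES = 32


@dataclass
class ParticipantScore:
    participant_id: str
    slice_scores: list[float]
    threshold: float

    @property
    def n_slices(self) -> int:
        return len(self.slice_scores)

    @property
    def participant_score(self) -> float:
        return max(self.slice_scores)

    @property
    def label_pred(self) -> str:
        return "positive" if self.participant_score >= self.threshold else "negative"


def lung_span(lung_mask: np.ndarray) -> tuple[int, int]:
    """First and last axial slice indices containing lung voxels."""
    has_lung = np.flatnonzero(lung_mask.any(axis=(1, 2)))
    if has_lung.size == 0:
        raise ValueError("lung mask is empty")
    return int(has_lung[0]), int(has_lung[-1])


def sample_slices(lung_mask: np.ndarray, n: int) -> list[int]:
    """n slice indices evenly spaced over the lung span, endpoints included.

    Indices come from rounding a linear spacing between the first and last
    lung-containing slice; they are strictly increasing. With n = 1 the
    midpoint slice is returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = lung_span(lung_mask)
    span = hi - lo + 1
    if span < n:
        raise ValueError(f"lungs span only {span} slices, cannot sample {n}")
    if n == 1:
        return [int(round((lo + hi) / 2))]
    idx = np.rint(np.linspace(lo, hi, n)).astype(int)
    return [int(i) for i in idx]


def classify_participant(
    slice_scores, threshold: float, participant_id: str = ""
) -> ParticipantScore:
    """Apply the all-slices rule: positive iff any slice score >= threshold."""
    scores = [float(s) for s in slice_scores]
    if not scores:
        raise ValueError("at least one slice score is required")
    return ParticipantScore(participant_id=participant_id, slice_scores=scores, threshold=float(threshold))


def choose_threshold(scores, labels, method: str = "youden") -> float:
    """Pick an operating threshold on a validation split.

    "youden" maximises sensitivity + specificity - 1 over all cut points
    (midpoints between adjacent distinct scores plus the extremes); ties
    are broken toward higher sensitivity (the lower threshold). If every
    score is identical the classes are inseparable and 0.5 is returned as
    a documented fallback.
    """
    if method != "youden":
        raise ValueError(f"unknown method: {method}")
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to choose a threshold")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return 0.5
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best_j, best_t, best_sens = -np.inf, None, -1.0
    for t in cands:
        pred = scores >= t
        sens = np.count_nonzero(pred & (y == 1)) / n_pos
        spec = np.count_nonzero(~pred & (y == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and sens > best_sens):
            best_j, best_t, best_sens = j, t, sens
    return float(best_t)
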