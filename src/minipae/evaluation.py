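"""Evaluation statistics for the screening classifier.

Confusion-matrix metrics, ROC-AUC with a percentile bootstrap confidence
interval (1,000 resamples by default), McNemar's paired test for comparing
classifiers on the same participants, and Cohen's kappa for agreement
between two categorisations. AUC goes through scikit-learn, McNemar
through statsmodels (exact binomial for few discordant pairs,
continuity-corrected chi-square otherwise) and kappa through scikit-learn;
the test suite keeps independent brute-force oracles for each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

#: discordant-pair count below which McNemar uses the exact binomial test
MCNEMAR_EXACT_MAX = 25


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    f1: float
    counts: ConfusionCounts
    n_bootstrap: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_lo": self.auc_ci[0],
            "auc_ci_hi": self.auc_ci[1],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
        }


def counts_from_predictions(labels, preds) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(preds, dtype=int)
    return ConfusionCounts(
        tp=int(np.count_nonzero((y == 1) & (p == 1))),
        fp=int(np.count_nonzero((y == 0) & (p == 1))),
        tn=int(np.count_nonzero((y == 0) & (p == 0))),
        fn=int(np.count_nonzero((y == 1) & (p == 0))),
    )


def metrics_from_counts(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, F1 and precision from confusion counts.

    F1 = 2TP / (2TP + FP + FN). When TP + FP = 0 precision is undefined
    and reported as 0.0 (and F1 is then 0 as well, unless there are no
    positives at all).
    """
    if counts.n_pos == 0 and counts.n_neg == 0:
        raise ValueError("empty confusion matrix")
    sens = counts.tp / counts.n_pos if counts.n_pos else float("nan")
    spec = counts.tn / counts.n_neg if counts.n_neg else float("nan")
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / denom if denom else 0.0
    precision = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 0.0
    return {"sensitivity": sens, "specificity": spec, "f1": f1, "precision": precision}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used for printed tables)."""
    factor = 10**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def roc_auc(labels, scores) -> float:
    """ROC-AUC; equals P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def bootstrap_auc_ci(labels, scores, n_iter: int = 1000, seed: int = 0, alpha: float = 0.05):
    """Percentile bootstrap CI for the AUC over participant-level resamples.

    Iterations whose resample contains a single class are redrawn.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(n_iter)
    for i in range(n_iter):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        aucs[i] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def mcnemar_test(correct_a, correct_b) -> tuple[float, float]:
    """McNemar's paired test on per-participant correctness of two classifiers.

    b = participants A got right and B got wrong; c = the reverse. Exact
    two-sided binomial test when b + c < 25, continuity-corrected
    chi-square otherwise. Zero discordant pairs gives p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    bvec = np.asarray(correct_b, dtype=bool)
    if a.shape != bvec.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.count_nonzero(a & ~bvec))
    c = int(np.count_nonzero(~a & bvec))
    if b + c == 0:
        return 0.0, 1.0
    both = int(np.count_nonzero(a & bvec))
    neither = int(np.count_nonzero(~a & ~bvec))
    table = [[both, b], [c, neither]]
    exact = (b + c) < MCNEMAR_EXACT_MAX
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cohens_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa with marginal-product expected agreement.

    Undefined (raises) when both raters are constant, since expected
    agreement is then 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1:
        raise ValueError("kappa undefined: both raters are constant")
    return float(cohen_kappa_score(a, b))


def evaluate(labels, scores, threshold: float, n_bootstrap: int = 1000, seed: int = 0) -> EvalReport:
    """Full report: confusion counts at a threshold plus AUC with bootstrap CI."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    preds = (s >= threshold).astype(int)
    counts = counts_from_predictions(y, preds)
    m = metrics_from_counts(counts)
    auc = roc_auc(y, s)
    ci = bootstrap_auc_ci(y, s, n_iter=n_bootstrap, seed=seed)
    return EvalReport(
        auc=auc,
        auc_ci=ci,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        f1=m["f1"],
        counts=counts,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
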