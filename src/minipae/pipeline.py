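"""End-to-end experimental protocol.

For each slab thickness, independently: project minIP stacks, sample
slices over the lung span, train the adversarial auto-encoder on slices
from the training normals only, score the validation participants, choose
an operating threshold (Youden's J on the validation scores) and produce
an evaluation report. The training split takes a fraction (default 80%)
of the non-emphysema participants; everyone else — held-out normals plus
all emphysema participants — forms the internal validation set. A final
comparison table lists one row per thickness, and McNemar's test compares
the two best-performing thicknesses on paired per-participant correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anomaly_model import (
    AnomalyModel,
    ModelConfig,
    build_model,
    calibrate_scores,
    raw_anomaly_scores,
    train,
)
from .densitometry import segment_lungs
from .evaluation import EvalReport, evaluate, mcnemar_test, roc_auc
from .minip import project_minip, slab_settings
from .phantom import LABEL_NORMAL
from .phantom import generate_cohort as generate_phantom_cohort
from .screening import choose_threshold, classify_participant, sample_slices
from .volume_io import MODEL_WINDOW_HU, normalize_hu


@dataclass
class ExperimentConfig:
    thicknesses_mm: tuple = (1, 3, 5, 7, 9, 11)
    train_frac: float = 0.8
    n_slices: int = 16
    model: ModelConfig = field(default_factory=ModelConfig)
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.thicknesses_mm = tuple(slab_settings(self.thicknesses_mm))
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


def split_cohort(manifest: pd.DataFrame, train_frac: float = 0.8, seed: int = 0):
    """Split a cohort manifest into training normals and internal validation.

    The training set holds ``train_frac`` of the non-emphysema participants
    (seeded shuffle); validation holds the remaining normals plus every
    emphysema participant. The two sets are disjoint and the training set
    never contains an emphysema label.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be strictly between 0 and 1 "
                         "(an empty validation set is not allowed)")
    labels = manifest["label"].to_numpy()
    normal_idx = np.flatnonzero(labels == LABEL_NORMAL)
    if len(normal_idx) < 2:
        raise ValueError("need at least 2 normal participants to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(normal_idx)
    n_train = int(round(train_frac * len(normal_idx)))
    n_train = min(n_train, len(normal_idx) - 1)  # keep validation non-empty
    train_idx = np.sort(order[:n_train])
    val_idx = np.sort(
        np.concatenate([order[n_train:], np.flatnonzero(labels != LABEL_NORMAL)])
    )
    train = manifest.iloc[train_idx].reset_index(drop=True)
    val = manifest.iloc[val_idx].reset_index(drop=True)
    if (train["label"] != LABEL_NORMAL).any():
        raise AssertionError("training split contains a non-normal label")
    assert not set(train["participant_id"]) & set(val["participant_id"])
    return train, val


@dataclass
class ThicknessResult:
    thickness_mm: float
    report: EvalReport
    threshold: float
    slice_auc: float
    participant_scores: pd.DataFrame
    model: AnomalyModel | None = None


@dataclass
class ExperimentResult:
    per_thickness: dict
    table: pd.DataFrame
    mcnemar: dict | None
    errors: dict = field(default_factory=dict)


def _participant_slices(vol, lung_mask, thickness_mm, n_slices):
    """Windowed minIP slices sampled over the lung span, with the matching
    per-slice lung masks."""
    stack = project_minip(vol, thickness_mm)
    idx = sample_slices(lung_mask, n_slices)
    slices = np.stack([normalize_hu(stack.slabs[i], MODEL_WINDOW_HU).pixels for i in idx])
    masks = np.stack([lung_mask[i] for i in idx])
    return slices, masks, idx


def run_experiment(cohort, config: ExperimentConfig, keep_models: bool = False) -> ExperimentResult:
    """Run the full per-thickness protocol on an in-memory cohort.

    ``cohort`` is a list of (CTVolume, PhantomTruth-like) pairs; only the
    truth's ``label`` is consumed (lung masks are recomputed by the
    densitometric segmenter, so the pipeline does not peek at ground-truth
    geometry). One failure is isolated per thickness: remaining
    thicknesses still run.
    """
    manifest = pd.DataFrame(
        {
            "participant_id": [v.participant_id for v, _ in cohort],
            "label": [t.label for _, t in cohort],
        }
    )
    train_df, val_df = split_cohort(manifest, config.train_frac, config.seed)
    by_id = {v.participant_id: (v, t) for v, t in cohort}
    lung_masks = {pid: segment_lungs(by_id[pid][0]).mask for pid in manifest["participant_id"]}

    per_thickness: dict = {}
    errors: dict = {}
    for t_i, thickness in enumerate(config.thicknesses_mm):
        try:
            per_thickness[thickness] = _run_one_thickness(
                thickness, t_i, train_df, val_df, by_id, lung_masks, config, keep_models
            )
        except Exception as exc:  # isolate per-thickness failures
            errors[thickness] = repr(exc)
    rows = []
    for thickness, res in per_thickness.items():
        r = res.report
        rows.append(
            {
                "thickness_mm": thickness,
                "auc": r.auc,
                "auc_ci_lo": r.auc_ci[0],
                "auc_ci_hi": r.auc_ci[1],
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "false_negative": r.counts.fn,
                "false_positive": r.counts.fp,
                "f1": r.f1,
                "slice_auc": res.slice_auc,
            }
        )
    table = pd.DataFrame(rows)
    comparison = None
    if len(per_thickness) >= 2:
        top = table.sort_values("auc", ascending=False)["thickness_mm"].iloc[:2].tolist()
        a, b = per_thickness[top[0]], per_thickness[top[1]]
        sa = a.participant_scores.set_index("participant_id")
        sb = b.participant_scores.set_index("participant_id")
        ids = sa.index
        stat, p = mcnemar_test(sa.loc[ids, "correct"], sb.loc[ids, "correct"])
        comparison = {"thicknesses": (top[0], top[1]), "statistic": stat, "p_value": p}
    return ExperimentResult(
        per_thickness=per_thickness, table=table, mcnemar=comparison, errors=errors
    )


def _run_one_thickness(thickness, t_i, train_df, val_df, by_id, lung_masks, config, keep_models):
    # thickness-derived sub-seed so each slab setting trains independently
    sub_seed = int(np.random.SeedSequence([config.seed, t_i]).generate_state(1)[0] % (2**31))
    mcfg = replace(config.model, seed=sub_seed)

    train_slices, train_masks = [], []
    for pid in train_df["participant_id"]:
        vol, _ = by_id[pid]
        sl, mk, _ = _participant_slices(vol, lung_masks[pid], thickness, config.n_slices)
        train_slices.append(sl)
        train_masks.append(mk)
    x_train = np.concatenate(train_slices)
    m_train = np.concatenate(train_masks)
    model = build_model(mcfg)
    train(model, x_train, labels=[LABEL_NORMAL] * len(x_train), config=mcfg)
    # calibrate the scorer on (a subsample of) the training normals
    cal_n = min(len(x_train), 240)
    calibrate_scores(model, x_train[:cal_n], m_train[:cal_n])

    val_slices, val_masks, owners, owner_label = [], [], [], {}
    for pid in val_df["participant_id"]:
        vol, truth = by_id[pid]
        sl, mk, _ = _participant_slices(vol, lung_masks[pid], thickness, config.n_slices)
        val_slices.append(sl)
        val_masks.append(mk)
        owners += [pid] * len(sl)
        owner_label[pid] = int(truth.label != LABEL_NORMAL)
    x_val = np.concatenate(val_slices)
    m_val = np.concatenate(val_masks)
    raws, _ = raw_anomaly_scores(model, x_val, lung_masks=m_val)
    lo, hi = raws.min(), raws.max()
    slice_scores = (raws - lo) / (hi - lo) if hi > lo else np.full_like(raws, 0.5)
    model.calibration = (float(lo), float(hi))

    owners = np.asarray(owners)
    pids = val_df["participant_id"].tolist()
    part_scores = np.array([slice_scores[owners == pid].max() for pid in pids])
    y = np.array([owner_label[pid] for pid in pids])
    slice_y = np.array([owner_label[o] for o in owners])

    slice_auc = roc_auc(slice_y, slice_scores)
    threshold = choose_threshold(part_scores, y, method="youden")
    report = evaluate(y, part_scores, threshold, n_bootstrap=config.n_bootstrap, seed=sub_seed)
    preds = [
        classify_participant(slice_scores[owners == pid], threshold, pid) for pid in pids
    ]
    scores_df = pd.DataFrame(
        {
            "participant_id": pids,
            "label": y,
            "participant_score": part_scores,
            "label_pred": [p.label_pred for p in preds],
            "correct": [(p.label_pred == "positive") == bool(lbl) for p, lbl in zip(preds, y)],
        }
    )
    return ThicknessResult(
        thickness_mm=float(thickness),
        report=report,
        threshold=float(threshold),
        slice_auc=float(slice_auc),
        participant_scores=scores_df,
        model=model if keep_models else None,
    )


def comparison_markdown(result: ExperimentResult) -> str:
    """Render the per-thickness comparison as a Markdown table."""
    lines = [
        "| Setting | AUC | 95% CI | Sensitivity | Specificity | FN | FP | F1 |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, r in result.table.sort_values("thickness_mm", ascending=False).iterrows():
        lines.append(
            f"| minIP {r.thickness_mm:g} | {r.auc:.2f} | "
            f"({r.auc_ci_lo:.2f}, {r.auc_ci_hi:.2f}) | {r.sensitivity:.2f} | "
            f"{r.specificity:.2f} | {int(r.false_negative)} | {int(r.false_positive)} | {r.f1:.2f} |"
        )
    if result.mcnemar:
        a, b = result.mcnemar["thicknesses"]
        lines.append(
            f"\nMcNemar minIP {a:g} vs minIP {b:g}: "
            f"p = {result.mcnemar['p_value']:.4f}"
        )
    return "\n".join(lines)


def _derived_seed(*keys) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def anomaly_benchmark(
    seed: int = 0,
    n_train_normal: int = 60,
    n_val_normal: int = 20,
    n_val_emphysema: int = 20,
    thicknesses_mm=(1, 11),
    n_slices: int = 10,
    model_config: ModelConfig | None = None,
) -> dict:
    """Train-and-evaluate benchmark on a phantom cohort, per slab thickness.

    Trains the adversarial auto-encoder on slices from normal phantoms
    only, scores a held-out mixed cohort and reports, for each slab
    thickness:

    * ``slice_auc_truth`` — slice-score ROC-AUC against exact slice-level
      ground truth (lesion present anywhere in the projected slab window);
    * ``slice_auc_participant`` — the same scores against participant
      labels (every slice of an emphysema participant counts positive,
      even lesion-free ones), the label the screening cohorts provide;
    * ``participant_auc`` — ROC-AUC of the participant score (max over
      slices);
    * ``detection_hit_rate`` — among truly positive slices that the
      slice-level classifier flags, the fraction whose detection map
      overlaps the true lesion mask (intersection > 0);
    * confusion counts of the participant-level screen at the Youden
      threshold.
    """
    from .anomaly_model import _erode2d
    from .detection import candidate_regions
    from .minip import mm_to_slices

    mcfg_base = model_config or ModelConfig()
    train_cohort = generate_phantom_cohort(n_train_normal, 0, seed=_derived_seed(seed, 101))
    val_cohort = generate_phantom_cohort(
        n_val_normal, n_val_emphysema, seed=_derived_seed(seed, 202)
    )
    masks_tr = [segment_lungs(v).mask for v, _ in train_cohort]
    masks_va = [segment_lungs(v).mask for v, _ in val_cohort]

    out = {}
    for t_i, thickness in enumerate(thicknesses_mm):
        k = mm_to_slices(thickness, train_cohort[0][0].slice_increment_mm)
        h = (k - 1) // 2

        x_tr, m_tr = [], []
        for (vol, _), lung in zip(train_cohort, masks_tr):
            sl, mk, _ = _participant_slices(vol, lung, thickness, n_slices)
            x_tr.append(sl)
            m_tr.append(mk)
        x_tr, m_tr = np.concatenate(x_tr), np.concatenate(m_tr)

        x_va, m_va, y_truth, y_part, owners, lesion_slabs = [], [], [], [], [], []
        for pi, ((vol, truth), lung) in enumerate(zip(val_cohort, masks_va)):
            sl, mk, idx = _participant_slices(vol, lung, thickness, n_slices)
            x_va.append(sl)
            m_va.append(mk)
            nz = vol.n_slices
            for i in idx:
                lo, hi = max(0, i - h), min(nz, i + h + 1)
                slab_lesion = truth.lesion_mask[lo:hi].any(axis=0)
                lesion_slabs.append(slab_lesion)
                y_truth.append(bool(slab_lesion.any()))
                y_part.append(truth.label != LABEL_NORMAL)
                owners.append(pi)
        x_va, m_va = np.concatenate(x_va), np.concatenate(m_va)
        y_truth = np.asarray(y_truth, dtype=int)
        y_part = np.asarray(y_part, dtype=int)
        owners = np.asarray(owners)

        mcfg = replace(mcfg_base, seed=_derived_seed(seed, 11, t_i))
        model = build_model(mcfg)
        train(model, x_tr, labels=[LABEL_NORMAL] * len(x_tr), config=mcfg)
        cal_n = min(len(x_tr), 240)
        calibrate_scores(model, x_tr[:cal_n], m_tr[:cal_n])

        raws, recons = raw_anomaly_scores(model, x_va, lung_masks=m_va)
        lo_r, hi_r = raws.min(), raws.max()
        scores = (raws - lo_r) / (hi_r - lo_r) if hi_r > lo_r else np.full_like(raws, 0.5)

        slice_auc_truth = roc_auc(y_truth, scores)
        slice_auc_part = roc_auc(y_part, scores)
        pids = np.unique(owners)
        p_scores = np.array([scores[owners == p].max() for p in pids])
        p_labels = np.array([y_part[owners == p][0] for p in pids])
        participant_auc = roc_auc(p_labels, p_scores)
        thr = choose_threshold(scores, y_truth)

        # detection maps on correctly flagged truly-positive slices.
        # Binarisation uses the emphysema-direction residual (X' - X)+ —
        # the reconstruction being brighter than the input marks abnormally
        # dark tissue — thresholded at the 95th percentile of normal-lung
        # values (vessel misplacement only produces dark-direction errors,
        # which a two-sided |X - X'| threshold would let dominate)
        cal_x = x_tr[:cal_n][:, None].astype(np.float32)
        cal_rec, _ = model.generator.forward(cal_x, train=False)
        cal_res = np.clip(cal_rec - cal_x, 0, None)[:, 0]
        cal_ero = [_erode2d(m_tr[i]) for i in range(cal_n)]
        lung_res = [cal_res[i][cal_ero[i]] for i in range(cal_n) if cal_ero[i].any()]
        tau_res = float(np.percentile(np.concatenate(lung_res), 95.0))
        hits = total = 0
        for i in range(len(scores)):
            if y_truth[i] and scores[i] >= thr:
                total += 1
                res = np.clip(recons[i] - x_va[i], 0, None)
                det = candidate_regions(res, _erode2d(m_va[i]), tau_res)
                if (det.candidate_mask & lesion_slabs[i]).any():
                    hits += 1
        hit_rate = hits / total if total else float("nan")

        p_thr = choose_threshold(p_scores, p_labels)
        preds = (p_scores >= p_thr).astype(int)
        counts = {
            "fn": int(((p_labels == 1) & (preds == 0)).sum()),
            "fp": int(((p_labels == 0) & (preds == 1)).sum()),
        }
        out[float(thickness)] = {
            "slice_auc_truth": float(slice_auc_truth),
            "slice_auc_participant": float(slice_auc_part),
            "participant_auc": float(participant_auc),
            "detection_hit_rate": float(hit_rate),
            "detection_hits": hits,
            "detection_total": total,
            "participant_counts": counts,
            "n_val_slices": int(len(scores)),
        }
    return out
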