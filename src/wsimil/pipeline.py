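"""End-to-end orchestration of the two-stage pipeline over a cohort directory.

Per fold: train the patch scorer on weakly labeled patches sampled from the
fold's training slides, score every ROI patch of every slide in the fold,
build top-K DS-ranked bags with the fold's scorer, train the attention-MIL
classifier (monitoring validation accuracy under ``kfold_holdout``, training
accuracy under ``ltocv``), and evaluate on the fold's held-out slides.  The
K-ablation harness reuses each fold's trained scorer across all K values, so
only the bag construction and the (cheap) MIL stage are re-run per K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (FoldMetrics, SplitPlan, aggregate_folds, compute_metrics,
                         make_splits)
from .mil import AttentionMILClassifier
from .sampling import Bag, build_bag
from .scorer import PatchScorer, build_patch_training_set, load_patch_images, score_slide
from .tiling import SlideRecord, build_manifest, load_slide_records

__all__ = ["StudyResult", "run_study", "ablate_k", "attention_truth_gap"]

# Desk-scale training schedule for synthetic cohorts; documented in the
# methods note.  Real-cohort defaults live on the estimators themselves.
_SCORER_DEFAULTS = dict(embed_dim=64, learning_rate=1e-3, max_epochs=16,
                        patience=5, batch_size=128)
_MIL_DEFAULTS = dict(learning_rate=3e-3, max_epochs=150, patience=15)


@dataclass
class StudyResult:
    plan: SplitPlan
    fold_metrics: list[FoldMetrics]
    predictions: pd.DataFrame
    summary: pd.DataFrame
    models: list = field(default_factory=list)   # (scorer, mil, bags_by_id) per fold


def _fold_seed(seed: int, fold_index: int, stream: int) -> int:
    state = np.random.SeedSequence([seed, fold_index, stream]).generate_state(1)
    return int(state[0] % (2 ** 31))


def _train_fold_scorer(slides_by_id, manifest, train_ids, seed, scorer_kwargs,
                       per_slide_train):
    train_slides = [slides_by_id[s] for s in train_ids]
    sub = manifest[manifest["slide_id"].isin(train_ids)]
    patch_df = build_patch_training_set(train_slides, sub, per_slide=per_slide_train,
                                        seed=seed)
    X = load_patch_images(train_slides, patch_df)
    scorer = PatchScorer(seed=seed, **scorer_kwargs)
    scorer.fit(X, patch_df["label"].to_numpy())
    return scorer


def _score_fold(scorer, slides_by_id, manifest, slide_ids):
    return {sid: score_slide(scorer, slides_by_id[sid], manifest)
            for sid in slide_ids}


def _bags_for(scorer, slides_by_id, scored, slide_ids, k) -> list[Bag]:
    bags = []
    for sid in slide_ids:
        df = scored[sid]
        bags.append(build_bag(scorer, slides_by_id[sid], df,
                              k=len(df) if k is None else k))
    return bags


def _fit_mil(train_bags, val_bags, monitor, seed, mil_kwargs):
    mil = AttentionMILClassifier(monitor=monitor, seed=seed, **mil_kwargs)
    if monitor == "validation_accuracy":
        mil.fit(train_bags, validation_bags=val_bags)
    else:
        mil.fit(train_bags)
    return mil


def _predict_bags(mil, bags, fold_index) -> pd.DataFrame:
    rows = []
    for bag in bags:
        pred = mil.predict_slide(bag)
        rows.append({"fold": fold_index, "slide_id": bag.slide_id, "label": bag.label,
                     "probability": pred.probability,
                     "predicted_label": pred.predicted_label})
    return pd.DataFrame(rows)


def run_study(cohort_root, patch_size: int = 64, k: int | None = 16,
              scheme: str = "kfold_holdout", n_folds: int = 5, seed: int = 0,
              test_fraction: float = 0.2, val_fraction: float = 0.1,
              per_slide_train: int = 32, scorer_kwargs: dict | None = None,
              mil_kwargs: dict | None = None, keep_models: bool = False) -> StudyResult:
    """Run the full cross-validated pipeline on a cohort directory.

    ``k=None`` disables sampling (every ROI patch enters the bag).  Under
    ``kfold_holdout`` metrics are computed on the shared hold-out test set per
    fold model; under ``ltocv`` on each fold's two validation slides, with a
    pooled summary.
    """
    cohort_root = Path(cohort_root)
    slides = load_slide_records(cohort_root)
    slides_by_id = {s.slide_id: s for s in slides}
    labels_df = pd.read_csv(cohort_root / "labels.csv")
    manifest = build_manifest(slides, patch_size)
    plan = make_splits(labels_df, scheme=scheme, n_folds=n_folds, seed=seed,
                       test_fraction=test_fraction, val_fraction=val_fraction)
    scorer_kwargs = {**_SCORER_DEFAULTS, **(scorer_kwargs or {})}
    mil_kwargs = {**_MIL_DEFAULTS, **(mil_kwargs or {})}
    monitor = "validation_accuracy" if scheme == "kfold_holdout" else "training_accuracy"

    fold_metrics, frames, models = [], [], []
    for fi, fold in enumerate(plan.folds):
        s_seed = _fold_seed(seed, fi, 0)
        m_seed = _fold_seed(seed, fi, 1)
        scorer = _train_fold_scorer(slides_by_id, manifest, fold.train_ids, s_seed,
                                    scorer_kwargs, per_slide_train)
        involved = list(fold.train_ids) + list(fold.val_ids) + list(fold.test_ids)
        scored = _score_fold(scorer, slides_by_id, manifest, involved)
        train_bags = _bags_for(scorer, slides_by_id, scored, fold.train_ids, k)
        val_bags = _bags_for(scorer, slides_by_id, scored, fold.val_ids, k)
        mil = _fit_mil(train_bags, val_bags, monitor, m_seed, mil_kwargs)
        eval_ids = fold.test_ids if scheme == "kfold_holdout" else fold.val_ids
        eval_bags = (_bags_for(scorer, slides_by_id, scored, fold.test_ids, k)
                     if scheme == "kfold_holdout" else val_bags)
        preds = _predict_bags(mil, eval_bags, fi)
        frames.append(preds)
        fold_metrics.append(compute_metrics(preds["label"], preds["probability"]))
        if keep_models:
            all_bags = {b.slide_id: b for b in train_bags + val_bags + eval_bags}
            models.append((scorer, mil, all_bags))

    predictions = pd.concat(frames, ignore_index=True)
    summary = aggregate_folds(fold_metrics, mode="mean_sd")
    return StudyResult(plan=plan, fold_metrics=fold_metrics, predictions=predictions,
                       summary=summary, models=models)


def ablate_k(cohort_root, k_values, patch_size: int = 64, scheme: str = "kfold_holdout",
             n_folds: int = 5, seed: int = 0, test_fraction: float = 0.2,
             val_fraction: float = 0.1, per_slide_train: int = 32,
             scorer_kwargs: dict | None = None,
             mil_kwargs: dict | None = None) -> pd.DataFrame:
    """AUC-vs-K table; each fold's scorer is shared across all K values.

    ``k_values`` entries may include ``None`` ("no sampling": every patch in
    the bag).  Returns one row per K with the per-fold and mean eval AUC.
    """
    cohort_root = Path(cohort_root)
    slides = load_slide_records(cohort_root)
    slides_by_id = {s.slide_id: s for s in slides}
    labels_df = pd.read_csv(cohort_root / "labels.csv")
    manifest = build_manifest(slides, patch_size)
    plan = make_splits(labels_df, scheme=scheme, n_folds=n_folds, seed=seed,
                       test_fraction=test_fraction, val_fraction=val_fraction)
    scorer_kwargs = {**_SCORER_DEFAULTS, **(scorer_kwargs or {})}
    mil_kwargs = {**_MIL_DEFAULTS, **(mil_kwargs or {})}
    monitor = "validation_accuracy" if scheme == "kfold_holdout" else "training_accuracy"

    aucs = {k: [] for k in k_values}
    for fi, fold in enumerate(plan.folds):
        s_seed = _fold_seed(seed, fi, 0)
        scorer = _train_fold_scorer(slides_by_id, manifest, fold.train_ids, s_seed,
                                    scorer_kwargs, per_slide_train)
        involved = list(fold.train_ids) + list(fold.val_ids) + list(fold.test_ids)
        scored = _score_fold(scorer, slides_by_id, manifest, involved)
        for ki, k in enumerate(k_values):
            m_seed = _fold_seed(seed, fi, 2 + ki)
            train_bags = _bags_for(scorer, slides_by_id, scored, fold.train_ids, k)
            val_bags = _bags_for(scorer, slides_by_id, scored, fold.val_ids, k)
            mil = _fit_mil(train_bags, val_bags, monitor, m_seed, mil_kwargs)
            eval_bags = (_bags_for(scorer, slides_by_id, scored, fold.test_ids, k)
                         if scheme == "kfold_holdout" else val_bags)
            preds = _predict_bags(mil, eval_bags, fi)
            aucs[k].append(compute_metrics(preds["label"], preds["probability"]).auc)

    rows = []
    for k in k_values:
        rows.append({"k": "all" if k is None else int(k),
                     "mean_auc": float(np.mean(aucs[k])),
                     "fold_aucs": [float(a) for a in aucs[k]]})
    return pd.DataFrame(rows)


def attention_truth_gap(mil: AttentionMILClassifier, bags: list[Bag],
                        truth: pd.DataFrame,
                        positive_kind: str = "discriminative_positive",
                        negative_kind: str = "discriminative_negative") -> float:
    """Mean attention gap between dense and sparse instances in positive slides.

    For every positive bag, look the ground-truth kind of each instance up in
    the simulator's sidecar and compare the mean attention on
    ``discriminative_positive`` (dense) instances with the mean attention on
    ``discriminative_negative`` (sparse) instances.  Positive values mean the
    trained attention concentrates on the instances that carry the label
    signal.  ``nondiscriminative`` instances are excluded from the contrast:
    their pixel content is drawn from a mixture straddling both class
    densities, so their sidecar kind does not determine their appearance and
    they belong to neither side of the oracle.  Slides whose bag lacks one of
    the two groups are skipped; the gap is the mean over the remaining
    positive slides.
    """
    kind_by_key = {(r.slide_id, r.x, r.y): r.kind for r in truth.itertuples()}
    gaps = []
    for bag in bags:
        if bag.label != 1:
            continue
        pred = mil.predict_slide(bag)
        kinds = np.array([kind_by_key.get((bag.slide_id, ref.x, ref.y), "unknown")
                          for ref in bag.refs])
        pos = kinds == positive_kind
        neg = kinds == negative_kind
        if pos.any() and neg.any():
            gaps.append(pred.attention[pos].mean() - pred.attention[neg].mean())
    if not gaps:
        raise ValueError("no positive bag contained both instance groups")
    return float(np.mean(gaps))
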