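"""Evaluation protocols: splits, metrics, aggregation, subgroups, heatmaps.

Two cross-validation schemes are provided.  ``kfold_holdout`` first balances
the cohort by downsampling the majority class, holds out a stratified test
set shared by every fold, then draws ``n_folds`` independent stratified
train/validation splits of the remainder (the reference protocol: 72/8 train/
validation with an 18-slide hold-out).  ``ltocv`` (leave-two-out CV) makes
one fold per slide pair, each validation set holding exactly one slide per
class, with no hold-out test set.

Metrics per fold are AUC (probability ranking), overall accuracy, per-class
recall ("low risk" / "high risk" accuracy) and macro F1; folds are aggregated
as mean +/- sample sd, or as percentile-bootstrap CIs over slide-level pooled
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, recall_score, roc_auc_score

__all__ = ["Fold", "SplitPlan", "FoldMetrics", "make_splits", "compute_metrics",
           "aggregate_folds", "percentile_bootstrap_ci", "subgroup_error_rates",
           "render_heatmap"]


@dataclass(frozen=True)
class Fold:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple = ()


@dataclass
class SplitPlan:
    scheme: str
    folds: list[Fold]
    seed: int
    balanced_ids: tuple = ()


@dataclass
class FoldMetrics:
    auc: float
    accuracy: float
    class0_accuracy: float
    class1_accuracy: float
    f1: float

    def as_dict(self) -> dict:
        return {"auc": self.auc, "accuracy": self.accuracy,
                "class0_accuracy": self.class0_accuracy,
                "class1_accuracy": self.class1_accuracy, "f1": self.f1}


def _balance(ids_by_class: dict[int, list], rng: np.random.Generator):
    """Downsample the majority class to the minority count (sorted input)."""
    n = min(len(v) for v in ids_by_class.values())
    out = {}
    for label, ids in ids_by_class.items():
        ids = sorted(ids)
        if len(ids) > n:
            keep = rng.choice(len(ids), size=n, replace=False)
            ids = [ids[i] for i in np.sort(keep)]
        out[label] = ids
    return out


def make_splits(labels: pd.DataFrame, scheme: str = "kfold_holdout",
                n_folds: int = 5, seed: int = 0, test_fraction: float = 0.2,
                val_fraction: float = 0.1) -> SplitPlan:
    """Build a cross-validation plan over a slide label table.

    ``labels`` needs columns ``slide_id`` and ``label``.  The cohort is first
    class-balanced by seeded downsampling of the majority class; splits are
    then drawn per scheme.  Deterministic under ``seed``.
    """
    if scheme not in ("kfold_holdout", "ltocv"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    by_class = {int(lab): grp["slide_id"].tolist()
                for lab, grp in labels.groupby("label")}
    if set(by_class) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    by_class = _balance(by_class, rng)
    n_per_class = len(by_class[0])

    if scheme == "ltocv":
        if n_per_class < 2:
            raise ValueError("ltocv needs at least 2 slides per class")
        lo = list(by_class[0]); hi = list(by_class[1])
        rng.shuffle(lo); rng.shuffle(hi)
        folds = []
        for i in range(n_per_class):
            val = (lo[i], hi[i])
            train = tuple(s for s in lo + hi if s not in val)
            folds.append(Fold(train_ids=train, val_ids=val))
        return SplitPlan("ltocv", folds, seed, tuple(sorted(lo + hi)))

    # kfold_holdout
    n_test = int(round(test_fraction * n_per_class))
    if n_per_class - n_test < n_folds and n_per_class - n_test < 2:
        raise ValueError("too few slides per class for the requested protocol")
    test_ids, rest = [], {}
    for label, ids in by_class.items():
        ids = list(ids)
        rng.shuffle(ids)
        test_ids.extend(ids[:n_test])
        rest[label] = ids[n_test:]
    test_ids = tuple(sorted(test_ids))
    n_val = max(1, int(round(val_fraction * len(rest[0]))))
    folds = []
    for _ in range(n_folds):
        val, train = [], []
        for label, ids in rest.items():
            ids = list(ids)
            rng.shuffle(ids)
            val.extend(ids[:n_val])
            train.extend(ids[n_val:])
        folds.append(Fold(train_ids=tuple(sorted(train)), val_ids=tuple(sorted(val)),
                          test_ids=test_ids))
    balanced = tuple(sorted(test_ids + tuple(rest[0]) + tuple(rest[1])))
    return SplitPlan("kfold_holdout", folds, seed, balanced)


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> FoldMetrics:
    """AUC, accuracy, per-class recall, macro F1 from slide probabilities."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = (p >= threshold).astype(int)
    return FoldMetrics(
        auc=float(roc_auc_score(y, p)),
        accuracy=float(accuracy_score(y, pred)),
        class0_accuracy=float(recall_score(y, pred, pos_label=0, zero_division=0)),
        class1_accuracy=float(recall_score(y, pred, pos_label=1, zero_division=0)),
        f1=float(f1_score(y, pred, average="macro", zero_division=0)),
    )


def percentile_bootstrap_ci(values, stat_fn=np.mean, B: int = 2000, seed: int = 0,
                            ci: float = 0.95):
    """Percentile bootstrap CI of a statistic over a 1-D sample."""
    values = np.asarray(values)
    n = len(values)
    if n == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    stats = np.array([stat_fn(values[row]) for row in idx])
    alpha = (1.0 - ci) / 2.0
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha))


def aggregate_folds(fold_metrics: list[FoldMetrics], mode: str = "mean_sd",
                    pooled: pd.DataFrame | None = None, B: int = 2000,
                    seed: int = 0, ci: float = 0.95) -> pd.DataFrame:
    """Aggregate per-fold metrics.

    ``mean_sd`` returns per-metric mean and sample standard deviation across
    folds.  ``bootstrap`` returns the point estimate on the pooled slide-level
    predictions (``pooled``: DataFrame with ``label`` and ``probability``)
    plus a percentile CI from ``B`` resamples of slides; resamples that lose a
    class are redrawn (AUC is undefined on them).
    """
    if not fold_metrics and mode == "mean_sd":
        raise ValueError("no fold metrics to aggregate")
    names = ["auc", "accuracy", "class0_accuracy", "class1_accuracy", "f1"]
    if mode == "mean_sd":
        table = np.array([[getattr(m, n) for n in names] for m in fold_metrics])
        sd = table.std(axis=0, ddof=1) if len(fold_metrics) > 1 else np.zeros(len(names))
        return pd.DataFrame({"metric": names, "mean": table.mean(axis=0), "sd": sd})
    if mode != "bootstrap":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if pooled is None or len(pooled) == 0:
        raise ValueError("bootstrap aggregation requires pooled slide predictions")
    y = pooled["label"].to_numpy().astype(int)
    p = pooled["probability"].to_numpy(dtype=np.float64)
    point = compute_metrics(y, p)
    rng = np.random.default_rng(seed)
    n = len(y)
    samples = {name: [] for name in names}
    for _ in range(B):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        m = compute_metrics(y[idx], p[idx])
        for name in names:
            samples[name].append(getattr(m, name))
    alpha = (1.0 - ci) / 2.0
    rows = []
    for name in names:
        s = np.asarray(samples[name])
        rows.append({"metric": name, "mean": getattr(point, name),
                     "ci_low": float(np.quantile(s, alpha)),
                     "ci_high": float(np.quantile(s, 1.0 - alpha))})
    return pd.DataFrame(rows)


def subgroup_error_rates(predictions: pd.DataFrame, covariates: pd.DataFrame,
                         grouping) -> pd.DataFrame:
    """Per-group error rate: misclassified / total within each covariate group.

    ``predictions`` needs ``slide_id``, ``label``, ``predicted_label``;
    ``covariates`` needs ``slide_id`` plus the grouping column.  ``grouping``
    is a column name, or ``(column, bin_edges)`` to bin a numeric covariate —
    bins with zero members are reported with an undefined (NaN) rate, not 0.
    """
    merged = predictions.merge(covariates, on="slide_id", how="inner")
    if isinstance(grouping, (tuple, list)) and len(grouping) == 2:
        column, edges = grouping
        if column not in merged.columns:
            raise KeyError(f"unknown grouping column {column!r}")
        groups = pd.cut(merged[column], bins=edges)
        categories = list(groups.cat.categories)
    else:
        column = grouping
        if column not in merged.columns:
            raise KeyError(f"unknown grouping column {column!r}")
        groups = merged[column]
        categories = sorted(groups.unique())
    rows = []
    wrong = merged["label"].astype(int) != merged["predicted_label"].astype(int)
    for cat in categories:
        mask = groups == cat
        n = int(mask.sum())
        n_err = int(wrong[mask].sum())
        rows.append({"group": str(cat), "n": n, "n_misclassified": n_err,
                     "error_rate": (n_err / n) if n else np.nan})
    return pd.DataFrame(rows)


def render_heatmap(slide_shape, refs, attention, downsample: int = 32,
                   enhance: bool = True) -> np.ndarray:
    """Paint per-patch attention back onto slide coordinates.

    Each patch footprint carries its attention weight at a ``downsample``-d
    resolution; overlapping footprints (stride < size) are averaged per
    pixel.  Unsampled/background regions stay at 0.  ``enhance`` applies the
    documented contrast stretch: clip footprint values at their 1st/99th
    percentiles, then min-max to [0, 1] (skipped when degenerate).
    """
    attention = np.asarray(attention, dtype=np.float64)
    if len(refs) != len(attention):
        raise ValueError("refs and attention must be aligned")
    h, w = slide_shape[:2]
    oh = int(np.ceil(h / downsample))
    ow = int(np.ceil(w / downsample))
    total = np.zeros((oh, ow))
    count = np.zeros((oh, ow))
    for ref, a in zip(refs, attention):
        y0 = ref.y // downsample
        x0 = ref.x // downsample
        y1 = int(np.ceil((ref.y + ref.size_px) / downsample))
        x1 = int(np.ceil((ref.x + ref.size_px) / downsample))
        total[y0:y1, x0:x1] += a
        count[y0:y1, x0:x1] += 1
    heat = np.zeros_like(total)
    footprint = count > 0
    heat[footprint] = total[footprint] / count[footprint]
    if enhance and footprint.any():
        vals = heat[footprint]
        lo, hi = np.percentile(vals, [1, 99])
        if hi > lo:
            heat[footprint] = (np.clip(vals, lo, hi) - lo) / (hi - lo)
    return heat
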