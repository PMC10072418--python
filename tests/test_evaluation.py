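"""Evaluation: split protocols, metric oracles, aggregation, subgroups, heatmaps."""

import numpy as np
import pandas as pd
import pytest

from wsimil import (PatchRef, aggregate_folds, compute_metrics, make_splits,
                    percentile_bootstrap_ci, render_heatmap, subgroup_error_rates)
from wsimil.evaluation import FoldMetrics


def label_table(n_low, n_high):
    rows = [{"slide_id": f"lo{i:03d}", "label": 0} for i in range(n_low)]
    rows += [{"slide_id": f"hi{i:03d}", "label": 1} for i in range(n_high)]
    return pd.DataFrame(rows)


class TestMakeSplits:
    def test_ltocv_balanced_25_per_class(self):
        plan = make_splits(label_table(25, 25), scheme="ltocv", seed=0)
        assert len(plan.folds) == 25
        for fold in plan.folds:
            assert len(fold.train_ids) == 48
            assert len(fold.val_ids) == 2
            labels = [0 if s.startswith("lo") else 1 for s in fold.val_ids]
            assert sorted(labels) == [0, 1]
            assert not set(fold.train_ids) & set(fold.val_ids)

    def test_ltocv_validation_sets_partition_cohort(self):
        plan = make_splits(label_table(10, 10), scheme="ltocv", seed=3)
        seen = [s for fold in plan.folds for s in fold.val_ids]
        assert sorted(seen) == sorted(plan.balanced_ids)

    def test_kfold_holdout_partition_invariants(self):
        for seed in range(25):
            plan = make_splits(label_table(20, 14), scheme="kfold_holdout",
                               n_folds=5, seed=seed)
            test = set(plan.folds[0].test_ids)
            for fold in plan.folds:
                assert set(fold.test_ids) == test           # shared hold-out
                train, val = set(fold.train_ids), set(fold.val_ids)
                assert not train & val
                assert not train & test and not val & test
                assert train | val | test == set(plan.balanced_ids)
            # balancing: equal class counts in the balanced cohort
            labels = [0 if s.startswith("lo") else 1 for s in plan.balanced_ids]
            assert sum(labels) == len(labels) - sum(labels) == 14

    def test_deterministic_under_seed(self):
        a = make_splits(label_table(12, 12), n_folds=3, seed=7)
        b = make_splits(label_table(12, 12), n_folds=3, seed=7)
        assert a.folds == b.folds
        c = make_splits(label_table(12, 12), n_folds=3, seed=8)
        assert a.folds != c.folds

    def test_errors(self):
        with pytest.raises(ValueError, match="scheme"):
            make_splits(label_table(4, 4), scheme="loocv")
        with pytest.raises(ValueError, match="both classes"):
            make_splits(label_table(5, 0))
        with pytest.raises(ValueError):
            make_splits(label_table(1, 1), scheme="ltocv")


def pairwise_auc(y, p):
    """O(n^2) probability-ranking oracle with half-credit for ties."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m.auc == m.accuracy == m.class0_accuracy == m.class1_accuracy == m.f1 == 1.0

    def test_uninformative_ties(self):
        m = compute_metrics([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert m.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            p = np.round(rng.random(n), 2)   # rounding makes ties likely
            m = compute_metrics(y, p)
            assert abs(m.auc - pairwise_auc(y, p)) < 1e-10

    def test_f1_matches_confusion_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            p = rng.random(n)
            pred = (p >= 0.5).astype(int)
            m = compute_metrics(y, p)

            def f1_for(cls):
                tp = int(((pred == cls) & (y == cls)).sum())
                fp = int(((pred == cls) & (y != cls)).sum())
                fn = int(((pred != cls) & (y == cls)).sum())
                return 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)

            assert m.f1 == pytest.approx((f1_for(0) + f1_for(1)) / 2, abs=1e-12)
            rec1 = ((pred == 1) & (y == 1)).sum() / max((y == 1).sum(), 1)
            assert m.class1_accuracy == pytest.approx(rec1, abs=1e-12)

    def test_accuracy_is_prevalence_weighted_class_accuracy(self):
        y = np.array([0, 0, 0, 1, 1])
        p = np.array([0.1, 0.6, 0.2, 0.9, 0.3])
        m = compute_metrics(y, p)
        w1 = y.mean()
        assert m.accuracy == pytest.approx((1 - w1) * m.class0_accuracy
                                           + w1 * m.class1_accuracy, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([1, 1, 1], [0.2, 0.4, 0.9])


class TestAggregateFolds:
    def test_mean_and_sample_sd(self):
        folds = [FoldMetrics(0.7, 0.7, 0.7, 0.7, 0.7),
                 FoldMetrics(0.9, 0.9, 0.9, 0.9, 0.9)]
        out = aggregate_folds(folds, mode="mean_sd").set_index("metric")
        assert out.loc["auc", "mean"] == pytest.approx(0.8)
        assert out.loc["auc", "sd"] == pytest.approx(np.std([0.7, 0.9], ddof=1))

    def test_identical_folds_zero_sd(self):
        folds = [FoldMetrics(0.8, 0.8, 0.8, 0.8, 0.8)] * 3
        out = aggregate_folds(folds, mode="mean_sd")
        np.testing.assert_allclose(out["sd"], 0.0, atol=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(0)
        n = 80
        y = np.repeat([0, 1], n // 2)
        p = np.clip(rng.normal(y * 0.6 + 0.2, 0.15), 0.01, 0.99)
        pooled = pd.DataFrame({"label": y, "probability": p})
        out = aggregate_folds([], mode="bootstrap", pooled=pooled, B=300,
                              seed=1).set_index("metric")
        for name in out.index:
            assert out.loc[name, "ci_low"] <= out.loc[name, "mean"] <= out.loc[name, "ci_high"]

    def test_errors(self):
        with pytest.raises(ValueError):
            aggregate_folds([], mode="mean_sd")
        with pytest.raises(ValueError):
            aggregate_folds([], mode="bootstrap", pooled=None)


class TestBootstrapCI:
    def test_degenerate_sample_zero_width(self):
        lo, hi = percentile_bootstrap_ci(np.ones(50), B=200, seed=0)
        assert lo == hi == 1.0

    def test_ci_contains_sample_mean_for_well_behaved_data(self):
        x = np.random.default_rng(3).normal(size=200)
        lo, hi = percentile_bootstrap_ci(x, B=500, seed=4)
        assert lo < x.mean() < hi


class TestSubgroupErrorRates:
    @staticmethod
    def tables():
        preds = pd.DataFrame({
            "slide_id": [f"s{i}" for i in range(8)],
            "label": [0, 0, 0, 0, 1, 1, 1, 1],
            "predicted_label": [0, 0, 0, 1, 1, 1, 1, 1],
        })
        cov = pd.DataFrame({
            "slide_id": [f"s{i}" for i in range(8)],
            "grade": [1, 1, 2, 2, 2, 3, 3, 3],
            "odx_score": [5, 10, 15, 20, 30, 40, 50, 60],
        })
        return preds, cov

    def test_all_correct_is_zero(self):
        preds, cov = self.tables()
        preds["predicted_label"] = preds["label"]
        out = subgroup_error_rates(preds, cov, "grade")
        assert (out["error_rate"] == 0).all()

    def test_rates_match_independent_tally(self):
        preds, cov = self.tables()
        out = subgroup_error_rates(preds, cov, "grade").set_index("group")
        merged = preds.merge(cov, on="slide_id")
        for grade, grp in merged.groupby("grade"):
            expected = (grp["label"] != grp["predicted_label"]).mean()
            assert out.loc[str(grade), "error_rate"] == pytest.approx(expected)
        # grade 2: one of three misclassified
        assert out.loc["2", "error_rate"] == pytest.approx(1 / 3)

    def test_empty_bin_is_nan_not_zero(self):
        preds, cov = self.tables()
        out = subgroup_error_rates(preds, cov, ("odx_score", [0, 25, 70, 100]))
        assert np.isnan(out.iloc[2]["error_rate"])
        assert out.iloc[2]["n"] == 0

    def test_unknown_grouping_key(self):
        preds, cov = self.tables()
        with pytest.raises(KeyError):
            subgroup_error_rates(preds, cov, "stage")


class TestRenderHeatmap:
    @staticmethod
    def refs(coords, size=32):
        return [PatchRef("s", y, x, size) for x, y in coords]

    def test_uniform_attention_constant_footprint(self):
        refs = self.refs([(0, 0), (32, 0), (0, 32), (32, 32)])
        heat = render_heatmap((64, 64), refs, np.full(4, 0.25), downsample=32,
                              enhance=False)
        np.testing.assert_allclose(heat, 0.25)

    def test_one_hot_lights_correct_cell(self):
        refs = self.refs([(0, 0), (32, 0), (0, 32), (32, 32)])
        a = np.array([0.0, 1.0, 0.0, 0.0])
        heat = render_heatmap((64, 64), refs, a, downsample=32, enhance=False)
        assert heat[0, 1] == 1.0
        assert heat.sum() == 1.0

    def test_background_stays_zero(self):
        refs = self.refs([(32, 32)])
        heat = render_heatmap((96, 96), refs, np.array([1.0]), downsample=32,
                              enhance=False)
        assert heat[1, 1] == 1.0
        assert heat.sum() == 1.0

    def test_overlapping_refs_averaged(self):
        refs = self.refs([(0, 0), (16, 0)], size=32)   # stride < size
        heat = render_heatmap((32, 48), refs, np.array([0.2, 0.8]), downsample=16,
                              enhance=False)
        np.testing.assert_allclose(heat[:, 0], 0.2)
        np.testing.assert_allclose(heat[:, 1], 0.5)   # overlap averaged
        np.testing.assert_allclose(heat[:, 2], 0.8)

    def test_contrast_stretch_maps_to_unit_interval(self):
        rng = np.random.default_rng(0)
        coords = [(32 * i, 32 * j) for i in range(8) for j in range(8)]
        a = rng.dirichlet(np.ones(64))
        heat = render_heatmap((256, 256), self.refs(coords), a, downsample=32)
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            render_heatmap((64, 64), self.refs([(0, 0)]), np.array([0.5, 0.5]))
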