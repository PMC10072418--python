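"""Gated attention MIL: pooling algebra, invariances, gradients, training."""

import numpy as np
import pytest
from scipy.optimize import linprog

from wsimil import AttentionMILClassifier, AttentionParams, attention_pool, attention_weights
from wsimil.mil import bag_loss_and_gradients

from conftest import make_gaussian_bags


def direct_gated_attention(X, params):
    """Element-by-element evaluation of the gating equation in extended precision."""
    Xl = X.astype(np.longdouble)
    V = params.V.astype(np.longdouble)
    U = params.U.astype(np.longdouble)
    w = params.w.astype(np.longdouble)
    K, L = Xl.shape[0], V.shape[0]
    s = np.zeros(K, dtype=np.longdouble)
    for k in range(K):
        total = np.longdouble(0)
        for l in range(L):
            zv = np.longdouble(0)
            zu = np.longdouble(0)
            for d in range(Xl.shape[1]):
                zv += V[l, d] * Xl[k, d]
                zu += U[l, d] * Xl[k, d]
            total += w[l] * np.tanh(zv) * (1 / (1 + np.exp(-zu)))
        s[k] = total
    e = np.exp(s - s.max())
    return (e / e.sum()).astype(np.float64)


@pytest.fixture()
def params():
    return AttentionParams.init(D=8, L=5, rng=np.random.default_rng(0))


class TestAttentionWeights:
    def test_singleton_bag(self, params):
        X = np.random.default_rng(1).normal(size=(1, 8))
        np.testing.assert_allclose(attention_weights(X, params), [1.0], atol=1e-15)

    def test_identical_instances_uniform(self, params):
        X = np.tile(np.random.default_rng(2).normal(size=(1, 8)), (6, 1))
        np.testing.assert_allclose(attention_weights(X, params), np.full(6, 1 / 6),
                                   atol=1e-12)

    def test_sums_to_one_and_nonnegative(self, params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = attention_weights(rng.normal(size=(7, 8)), params)
            assert a.sum() == pytest.approx(1.0, abs=1e-12)
            assert (a >= 0).all()

    def test_matches_direct_extended_precision_evaluation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            K, D, L = rng.integers(1, 9), rng.integers(2, 17), rng.integers(1, 9)
            p = AttentionParams.init(D=int(D), L=int(L), rng=rng)
            X = rng.normal(size=(K, D))
            a = attention_weights(X, p)
            np.testing.assert_allclose(a, direct_gated_attention(X, p), atol=1e-6)

    def test_dimension_mismatch(self, params):
        with pytest.raises(ValueError, match="dimension"):
            attention_weights(np.zeros((3, 5)), params)


class TestAttentionPool:
    def test_identical_rows_returns_the_point(self):
        x = np.random.default_rng(0).normal(size=8)
        X = np.tile(x, (4, 1))
        a = np.array([0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(attention_pool(X, a), x, atol=1e-12)

    def test_one_hot_selects_row(self):
        X = np.random.default_rng(1).normal(size=(5, 8))
        a = np.zeros(5)
        a[3] = 1.0
        np.testing.assert_allclose(attention_pool(X, a), X[3], atol=1e-15)

    def test_meta_instance_in_convex_hull(self):
        # LP feasibility: find weights on the simplex reproducing M from rows
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        a = rng.dirichlet(np.ones(6))
        M = attention_pool(X, a)
        res = linprog(c=np.zeros(6),
                      A_eq=np.vstack([X.T, np.ones(6)]),
                      b_eq=np.concatenate([M, [1.0]]),
                      bounds=[(0, 1)] * 6, method="highs")
        assert res.success

    def test_simplex_violation_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError):
            attention_pool(X, np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValueError):
            attention_pool(X, np.array([1.2, -0.2, 0.0]))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        params = AttentionParams.init(D=6, L=4, rng=rng)
        cw = rng.normal(size=6)
        cb = 0.3
        X = rng.normal(size=(5, 6))
        y = 1.0
        _, _, grads = bag_loss_and_gradients(params, cw, cb, X, y)
        eps = 1e-6
        for name in ("V_dir", "V_g", "U_dir", "U_g", "w"):
            arr = getattr(params, name)
            fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                lp = bag_loss_and_gradients(params, cw, cb, X, y)[0]
                arr[i] = orig - eps
                lm = bag_loss_and_gradients(params, cw, cb, X, y)[0]
                arr[i] = orig
                fd[i] = (lp - lm) / (2 * eps)
            denom = np.maximum(np.abs(fd), 1e-8)
            assert (np.abs(grads[name] - fd) / denom).max() < 1e-4, name

    def test_weight_norm_reconstruction(self):
        params = AttentionParams.init(D=10, L=6, rng=np.random.default_rng(6))
        V = params.V
        norms = np.linalg.norm(params.V_dir, axis=1, keepdims=True)
        np.testing.assert_allclose(V, params.V_g[:, None] * params.V_dir / norms,
                                   atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(V, axis=1), params.V_g, atol=1e-9)


@pytest.fixture(scope="module")
def fitted_mil():
    bags = make_gaussian_bags(n_per_class=12, k=8, d=6, seed=3)
    model = AttentionMILClassifier(attention_dim=4, learning_rate=5e-3,
                                   max_epochs=60, patience=10,
                                   monitor="training_accuracy", seed=0)
    return model.fit(bags), bags


class TestTraining:
    def test_separable_bags_reach_high_accuracy(self, fitted_mil):
        model, bags = fitted_mil
        assert model.best_monitor_ >= 0.95
        y = np.array([b.label for b in bags])
        assert np.mean(model.predict(bags) == y) >= 0.95

    def test_patience_zero_runs_one_epoch(self, gaussian_bags):
        model = AttentionMILClassifier(monitor="training_accuracy", max_epochs=10,
                                       patience=0, seed=0).fit(gaussian_bags)
        assert model.n_epochs_ == 1

    def test_loss_trace_reproducible(self, gaussian_bags):
        kwargs = dict(monitor="training_accuracy", max_epochs=5, patience=4, seed=9)
        a = AttentionMILClassifier(**kwargs).fit(gaussian_bags)
        b = AttentionMILClassifier(**kwargs).fit(gaussian_bags)
        assert [h["loss"] for h in a.history_] == [h["loss"] for h in b.history_]

    def test_validation_monitor_requires_validation_bags(self, gaussian_bags):
        with pytest.raises(ValueError, match="validation"):
            AttentionMILClassifier(monitor="validation_accuracy").fit(gaussian_bags)

    def test_single_class_rejected(self, gaussian_bags):
        neg = [b for b in gaussian_bags if b.label == 0]
        with pytest.raises(ValueError, match="both classes"):
            AttentionMILClassifier(monitor="training_accuracy").fit(neg)

    def test_weight_norm_holds_after_training(self, fitted_mil):
        model, _ = fitted_mil
        p = model.params_
        norms = np.linalg.norm(p.V_dir, axis=1, keepdims=True)
        np.testing.assert_allclose(p.V, p.V_g[:, None] * p.V_dir / norms, atol=1e-6)
        assert (p.V_g > 0).all() and (p.U_g > 0).all()


class TestPrediction:
    def test_permutation_invariance(self, fitted_mil):
        model, bags = fitted_mil
        rng = np.random.default_rng(0)
        for bag in bags[:5]:
            base = model.predict_slide(bag)
            for _ in range(20):
                perm = rng.permutation(len(bag.refs))
                shuffled = bag.instances[perm]
                pred = model.predict_slide(shuffled)
                assert pred.probability == pytest.approx(base.probability, abs=1e-6)
                np.testing.assert_allclose(pred.attention, base.attention[perm],
                                           atol=1e-6)

    def test_duplicating_instances_preserves_probability(self, fitted_mil):
        model, bags = fitted_mil
        for bag in bags[:5]:
            base = model.predict_slide(bag)
            doubled = np.vstack([bag.instances, bag.instances])
            pred = model.predict_slide(doubled)
            assert pred.probability == pytest.approx(base.probability, abs=1e-6)
            np.testing.assert_allclose(pred.attention,
                                       np.concatenate([base.attention] * 2) / 2,
                                       atol=1e-6)

    def test_attention_simplex_everywhere(self, fitted_mil):
        model, bags = fitted_mil
        for bag in bags:
            pred = model.predict_slide(bag)
            assert pred.attention.sum() == pytest.approx(1.0, abs=1e-6)
            assert (pred.attention >= 0).all()

    def test_zero_classifier_gives_half(self, fitted_mil):
        model, bags = fitted_mil
        import copy
        m = copy.deepcopy(model)
        m.classifier_w_ = np.zeros_like(m.classifier_w_)
        m.classifier_b_ = 0.0
        assert m.predict_slide(bags[0]).probability == pytest.approx(0.5, abs=1e-12)

    def test_classify_meta_monotone_in_logit(self, fitted_mil):
        model, _ = fitted_mil
        direction = model.classifier_w_ / np.linalg.norm(model.classifier_w_)
        probs = [model.classify_meta(t * direction) for t in (-2, -1, 0, 1, 2)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_unfitted_prediction_rejected(self, gaussian_bags):
        with pytest.raises(ValueError, match="not fitted"):
            AttentionMILClassifier().predict_slide(gaussian_bags[0])

    def test_save_load_roundtrip(self, fitted_mil, tmp_path):
        model, bags = fitted_mil
        path = tmp_path / "mil.npz"
        model.save(path)
        loaded = AttentionMILClassifier.load(path)
        for bag in bags[:4]:
            assert loaded.predict_slide(bag).probability == pytest.approx(
                model.predict_slide(bag).probability, abs=1e-12)
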