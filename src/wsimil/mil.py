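"""Gated attention-based multiple instance learning.

A slide is a bag of K instance embeddings ``x_k`` (rows of a K x D matrix).
The attention network scores each instance with a two-layer gated ANN,

    a_k = softmax_k( w^T ( tanh(V x_k^T) * sigm(U x_k^T) ) ),

(* is the element-wise product; V, U are L x D, w is L x 1), pools the bag
into a meta-instance ``M = sum_k a_k x_k`` and classifies M with a single
fully connected layer followed by a sigmoid.  The whole model is trained
end-to-end with binary cross-entropy, one Adam step per bag.

V and U are stored in weight-normalized form — each row is a positive scale
times a unit direction — which stabilizes optimization; the effective
matrices are reconstructed on every forward pass, so the reparameterization
holds exactly after every optimizer step.  All computation is float64: bags
are small once patches are embedded, so precision is cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .sampling import Bag

__all__ = ["AttentionParams", "Prediction", "AttentionMILClassifier",
           "attention_weights", "attention_pool", "bag_loss_and_gradients"]

_SIMPLEX_TOL = 1e-6


@dataclass
class AttentionParams:
    """Gated-attention parameters with V, U in weight-normalized storage."""

    V_dir: np.ndarray   # (L, D) direction tensor
    V_g: np.ndarray     # (L,) positive per-row scales
    U_dir: np.ndarray
    U_g: np.ndarray
    w: np.ndarray       # (L,)
    bv: np.ndarray | None = None   # optional gate biases (L,), off by default
    bu: np.ndarray | None = None

    @staticmethod
    def _effective(direction: np.ndarray, g: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(direction, axis=1, keepdims=True)
        return g[:, None] * direction / norms

    @property
    def V(self) -> np.ndarray:
        """Effective V = scale x unit-direction, row-wise."""
        return self._effective(self.V_dir, self.V_g)

    @property
    def U(self) -> np.ndarray:
        return self._effective(self.U_dir, self.U_g)

    @property
    def L(self) -> int:
        return self.V_dir.shape[0]

    @property
    def D(self) -> int:
        return self.V_dir.shape[1]

    @classmethod
    def init(cls, D: int, L: int, rng: np.random.Generator,
             use_gate_bias: bool = False) -> "AttentionParams":
        V_dir = rng.normal(0.0, 1.0 / np.sqrt(D), size=(L, D))
        U_dir = rng.normal(0.0, 1.0 / np.sqrt(D), size=(L, D))
        return cls(
            V_dir=V_dir, V_g=np.linalg.norm(V_dir, axis=1),
            U_dir=U_dir, U_g=np.linalg.norm(U_dir, axis=1),
            w=rng.normal(0.0, 1.0 / np.sqrt(L), size=L),
            bv=np.zeros(L) if use_gate_bias else None,
            bu=np.zeros(L) if use_gate_bias else None,
        )


@dataclass
class Prediction:
    """Slide-level output: probability, attention over instances, meta-instance."""

    slide_id: str
    probability: float
    attention: np.ndarray
    meta_instance: np.ndarray

    def __post_init__(self):
        a = self.attention
        if np.any(a < -_SIMPLEX_TOL) or abs(a.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("attention weights must lie on the probability simplex")

    @property
    def predicted_label(self) -> int:
        return int(self.probability >= 0.5)


def _as_matrix(bag) -> np.ndarray:
    X = bag.instances if isinstance(bag, Bag) else np.asarray(bag)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError(f"bag must be a non-empty K x D matrix, got shape {X.shape}")
    return X


def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max())
    return e / e.sum()


def _attention_forward(X: np.ndarray, params: AttentionParams):
    """Returns (a, cache) for a K x D bag."""
    if X.shape[1] != params.D:
        raise ValueError(f"bag dimension {X.shape[1]} != attention D={params.D}")
    Wv, Wu = params.V, params.U
    Zv = X @ Wv.T
    Zu = X @ Wu.T
    if params.bv is not None:
        Zv = Zv + params.bv
        Zu = Zu + params.bu
    H = np.tanh(Zv)
    G = nn.sigmoid(Zu)
    s = (H * G) @ params.w
    a = _softmax(s)
    return a, (H, G, Wv, Wu)


def attention_weights(bag, params: AttentionParams) -> np.ndarray:
    """Gated-attention weights of a bag: softmax over instances, sums to 1."""
    a, _ = _attention_forward(_as_matrix(bag), params)
    return a


def attention_pool(bag, a: np.ndarray) -> np.ndarray:
    """Meta-instance ``M = sum_k a_k x_k`` (a convex combination of rows)."""
    X = _as_matrix(bag)
    a = np.asarray(a, dtype=np.float64)
    if a.shape != (X.shape[0],):
        raise ValueError(f"attention length {a.shape} does not match bag rows {X.shape[0]}")
    if np.any(a < -_SIMPLEX_TOL) or abs(a.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError("attention weights must lie on the probability simplex")
    return a @ X


def _weight_norm_backward(dW, direction, g):
    """Chain dL/dW into (dL/d_direction, dL/d_g) for W = g * dir/||dir||."""
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    dirhat = direction / norms
    dg = np.sum(dW * dirhat, axis=1)
    ddir = (g[:, None] / norms) * (dW - dg[:, None] * dirhat)
    return ddir, dg


def bag_loss_and_gradients(params: AttentionParams, cw: np.ndarray, cb: float,
                           X: np.ndarray, y: float):
    """Binary cross-entropy of one bag and its gradients.

    Gradients are with respect to the stored parameters (weight-norm
    directions and scales, w, classifier weight/bias).  Returns
    ``(loss, probability, grads)`` with grads keyed ``V_dir, V_g, U_dir, U_g,
    w, bv, bu, cw, cb`` (gate-bias entries present only when biases are on).
    """
    X = _as_matrix(X)
    a, (H, G, _, _) = _attention_forward(X, params)
    M = a @ X
    logit = float(M @ cw + cb)
    p = float(nn.sigmoid(np.array(logit)))
    loss = max(logit, 0.0) - logit * y + np.log1p(np.exp(-abs(logit)))

    dlogit = p - y
    grads = {"cw": dlogit * M, "cb": dlogit}
    dM = dlogit * cw
    da = X @ dM
    ds = a * (da - a @ da)          # softmax backward
    HG = H * G
    grads["w"] = HG.T @ ds
    dHG = np.outer(ds, params.w)
    dH = dHG * G
    dG = dHG * H
    dZv = dH * (1.0 - H * H)
    dZu = dG * G * (1.0 - G)
    dWv = dZv.T @ X
    dWu = dZu.T @ X
    grads["V_dir"], grads["V_g"] = _weight_norm_backward(dWv, params.V_dir, params.V_g)
    grads["U_dir"], grads["U_g"] = _weight_norm_backward(dWu, params.U_dir, params.U_g)
    if params.bv is not None:
        grads["bv"] = dZv.sum(axis=0)
        grads["bu"] = dZu.sum(axis=0)
    return float(loss), p, grads


class AttentionMILClassifier(ClassifierMixin, BaseEstimator):
    """Slide-level classifier: gated attention pooling + one FC layer.

    scikit-learn style: :meth:`fit` takes a list of bags (``Bag`` objects or
    K x D arrays) and binary labels, :meth:`predict_proba` returns slide
    probabilities, :meth:`predict_slide` additionally exposes the attention
    vector and meta-instance for interpretability.

    Training performs one Adam step per bag (bags have heterogeneous K, so
    there is no batching across bags) and early-stops on the monitored
    accuracy — ``validation_accuracy`` (requires ``validation_bags``) or
    ``training_accuracy`` — with the given patience.  The checkpoint is the
    first occurrence of the best monitor value; ties do not reset patience.

    Parameters
    ----------
    attention_dim : int or None
        Hidden width L of the gated-attention ANN (default ``D // 2``; the
        1024-dim real-cohort configuration uses L = 512).
    use_gate_bias : bool
        Add bias terms to the V/U gate layers (off by default; the gating
        equation has none).
    """

    def __init__(self, attention_dim=None, learning_rate=2e-4, max_epochs=150,
                 patience=15, monitor="validation_accuracy", use_gate_bias=False,
                 seed=0):
        self.attention_dim = attention_dim
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.monitor = monitor
        self.use_gate_bias = use_gate_bias
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _bags_labels(bags, labels):
        mats = [_as_matrix(b) for b in bags]
        if labels is None:
            if not all(isinstance(b, Bag) for b in bags):
                raise ValueError("labels required when bags are plain arrays")
            labels = [b.label for b in bags]
        y = np.asarray(labels, dtype=np.float64).ravel()
        if len(y) != len(mats):
            raise ValueError("bags and labels length mismatch")
        return mats, y

    def _accuracy(self, mats, y):
        preds = np.array([self._forward_prob(X) >= 0.5 for X in mats])
        return float(np.mean(preds == (y > 0.5)))

    def _mean_loss(self, mats, y):
        probs = np.clip([self._forward_prob(X) for X in mats], 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(probs) + (1 - y) * np.log(1 - probs)))

    def _forward_prob(self, X) -> float:
        a, _ = _attention_forward(X, self.params_)
        logit = float((a @ X) @ self.classifier_w_ + self.classifier_b_)
        return float(nn.sigmoid(np.array(logit)))

    # -- training ----------------------------------------------------------
    def fit(self, bags, labels=None, validation_bags=None, validation_labels=None):
        mats, y = self._bags_labels(bags, labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training bags must contain both classes")
        if self.monitor not in ("validation_accuracy", "training_accuracy"):
            raise ValueError(f"unknown monitor {self.monitor!r}")
        if self.monitor == "validation_accuracy":
            if validation_bags is None:
                raise ValueError("monitor='validation_accuracy' requires validation_bags")
            val_mats, val_y = self._bags_labels(validation_bags, validation_labels)
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

        D = mats[0].shape[1]
        if any(X.shape[1] != D for X in mats):
            raise ValueError("all bags must share the same embedding dimension")
        L = int(self.attention_dim) if self.attention_dim is not None else max(D // 2, 1)
        rng = np.random.default_rng(self.seed)
        params = AttentionParams.init(D, L, rng, use_gate_bias=self.use_gate_bias)
        self.params_ = params
        self.classifier_w_ = rng.normal(0.0, 1.0 / np.sqrt(D), size=D)
        self.classifier_b_ = 0.0

        # Adam state over named parameter slots
        slot_names = ["V_dir", "V_g", "U_dir", "U_g", "w", "cw"]
        if self.use_gate_bias:
            slot_names += ["bv", "bu"]

        def get(name):
            if name == "cw":
                return self.classifier_w_
            return getattr(params, name)

        grad_bufs = {n: np.zeros_like(get(n)) for n in slot_names}
        grad_cb = np.zeros(1)
        cb_buf = np.array([0.0])
        opt = nn.Adam([(get(n), grad_bufs[n]) for n in slot_names] + [(cb_buf, grad_cb)],
                      lr=self.learning_rate)

        n = len(mats)
        best, best_loss, best_state, since = -np.inf, np.inf, None, 0
        history = []
        for epoch in range(int(self.max_epochs)):
            order = rng.permutation(n)
            losses = []
            for i in order:
                loss, _, grads = bag_loss_and_gradients(
                    params, self.classifier_w_, float(cb_buf[0]), mats[i], y[i])
                for name in slot_names:
                    grad_bufs[name][...] = grads[name]
                grad_cb[0] = grads["cb"]
                opt.step()
                losses.append(loss)
            self.classifier_b_ = float(cb_buf[0])
            if self.monitor == "validation_accuracy":
                monitor_val = self._accuracy(val_mats, val_y)
                monitor_loss = self._mean_loss(val_mats, val_y)
            else:
                monitor_val = self._accuracy(mats, y)
                monitor_loss = float(np.mean(losses))
            history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                            "monitor": monitor_val, "monitor_loss": monitor_loss})
            # strict accuracy improvement resets patience; among accuracy ties
            # the checkpoint moves to the lower-loss model without resetting it
            if monitor_val > best:
                best, best_loss, since = monitor_val, monitor_loss, 0
                best_state = self._snapshot()
            else:
                if monitor_val == best and monitor_loss < best_loss:
                    best_loss = monitor_loss
                    best_state = self._snapshot()
                since += 1
            if since >= self.patience:
                break
        self._restore(best_state)
        self.classes_ = np.array([0, 1])
        self.history_ = history
        self.n_epochs_ = len(history)
        self.best_monitor_ = float(best)
        return self

    def _snapshot(self):
        p = self.params_
        state = {"V_dir": p.V_dir.copy(), "V_g": p.V_g.copy(),
                 "U_dir": p.U_dir.copy(), "U_g": p.U_g.copy(), "w": p.w.copy(),
                 "cw": self.classifier_w_.copy(), "cb": self.classifier_b_}
        if p.bv is not None:
            state["bv"], state["bu"] = p.bv.copy(), p.bu.copy()
        return state

    def _restore(self, state):
        p = self.params_
        p.V_dir[...] = state["V_dir"]; p.V_g[...] = state["V_g"]
        p.U_dir[...] = state["U_dir"]; p.U_g[...] = state["U_g"]
        p.w[...] = state["w"]
        self.classifier_w_[...] = state["cw"]
        self.classifier_b_ = float(state["cb"])
        if p.bv is not None:
            p.bv[...] = state["bv"]; p.bu[...] = state["bu"]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise ValueError("AttentionMILClassifier is not fitted yet; call fit first")

    # -- inference ---------------------------------------------------------
    def classify_meta(self, meta: np.ndarray) -> float:
        """Probability from a precomputed meta-instance."""
        self._check_fitted()
        logit = float(np.asarray(meta, dtype=np.float64) @ self.classifier_w_
                      + self.classifier_b_)
        return float(nn.sigmoid(np.array(logit)))

    def predict_slide(self, bag) -> Prediction:
        """Full per-slide output: probability, attention vector, meta-instance."""
        self._check_fitted()
        X = _as_matrix(bag)
        a, _ = _attention_forward(X, self.params_)
        M = a @ X
        return Prediction(
            slide_id=bag.slide_id if isinstance(bag, Bag) else "",
            probability=self.classify_meta(M), attention=a, meta_instance=M)

    def predict_proba(self, bags) -> np.ndarray:
        self._check_fitted()
        p1 = np.array([self._forward_prob(_as_matrix(b)) for b in bags])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, bags) -> np.ndarray:
        return (self.predict_proba(bags)[:, 1] >= 0.5).astype(int)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        self._check_fitted()
        state = self._snapshot()
        config = json.dumps(self.get_params())
        np.savez(path, __config__=np.frombuffer(config.encode(), dtype=np.uint8),
                 **{k: np.asarray(v) for k, v in state.items()})

    @classmethod
    def load(cls, path) -> "AttentionMILClassifier":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            model = cls(**config)
            model.params_ = AttentionParams(
                V_dir=data["V_dir"], V_g=data["V_g"],
                U_dir=data["U_dir"], U_g=data["U_g"], w=data["w"],
                bv=data["bv"] if "bv" in data.files else None,
                bu=data["bu"] if "bu" in data.files else None)
            model.classifier_w_ = data["cw"]
            model.classifier_b_ = float(data["cb"])
        model.classes_ = np.array([0, 1])
        return model
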