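"""Patch-level CNN scorer and discrimination score.

The scorer is trained under weak supervision: every patch inherits its
slide-level risk label.  Its sigmoid output ``p`` is a patch's probability of
belonging to the high-risk class, and the discrimination score

    DS = |p - 0.5| / 0.5  in [0, 1]

measures the distance from the decision boundary: patches the scorer is
confident about (for either class) are discriminative, patches near p = 0.5
are not.  DS is later used to rank and sample patches per slide.

Two backbones are defined.  ``small_cnn`` is a three-conv-block network
(default 64-dim embedding) that trains on a CPU in seconds and is the fully
supported backbone.  ``paper_backbone`` names the ImageNet-pretrained
truncated-ResNet50 configuration (1024-dim embedding) used with real
whole-slide cohorts; it requires pretrained weights that this package does
not bundle, so constructing it raises with a clear message.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import nn
from .tiling import PatchRef, read_patch

__all__ = ["PatchScorer", "discrimination_score", "build_patch_training_set",
           "load_patch_images", "score_slide"]

# fixed input normalization: uint8 -> zero-mean, unit-ish scale
_PIXEL_MEAN = 0.5
_PIXEL_SCALE = 0.25


def discrimination_score(probability):
    """DS = |p - 0.5| / 0.5, elementwise; domain [0, 1], range [0, 1]."""
    p = np.asarray(probability, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability must lie in [0, 1]")
    ds = np.abs(p - 0.5) / 0.5
    return float(ds) if np.isscalar(probability) or p.ndim == 0 else ds


def build_patch_training_set(slides, manifest: pd.DataFrame, per_slide: int = 200,
                             seed: int = 0) -> pd.DataFrame:
    """Sample up to ``per_slide`` ROI patches per training slide, weakly labeled.

    Sampling is uniform without replacement within each slide; if a slide has
    fewer patches than ``per_slide`` all of them are used.  Each sampled patch
    carries its slide-level label.  Deterministic under ``seed``.
    """
    if manifest is None or len(manifest) == 0:
        raise ValueError("empty patch manifest")
    rng = np.random.default_rng(seed)
    labels = {s.slide_id: s.label for s in slides}
    out = []
    for slide_id, group in manifest.groupby("slide_id", sort=True):
        if slide_id not in labels:
            continue
        n = min(per_slide, len(group))
        take = rng.choice(len(group), size=n, replace=False)
        sub = group.iloc[np.sort(take)].copy()
        sub["label"] = labels[slide_id]
        out.append(sub)
    if not out:
        raise ValueError("manifest contains no patches for the given slides")
    return pd.concat(out, ignore_index=True)


def load_patch_images(slides, patch_table: pd.DataFrame) -> np.ndarray:
    """Stack the pixel windows of a patch table into one (N, s, s, 3) array."""
    by_id = {s.slide_id: s for s in slides}
    imgs = []
    for row in patch_table.itertuples():
        slide = by_id[row.slide_id]
        ref = PatchRef(row.slide_id, int(row.y), int(row.x), int(row.size_px))
        imgs.append(read_patch(slide, ref))
    return np.stack(imgs)


class PatchScorer(TransformerMixin, ClassifierMixin, BaseEstimator):
    """Weakly supervised patch classifier with a feature-extractor trunk.

    Follows the scikit-learn estimator protocol: :meth:`fit` on patch images
    and binary labels, :meth:`predict_proba` for class probabilities,
    :meth:`transform` for embeddings (the trunk output, used to build MIL
    bags).  Training minimizes binary cross-entropy with Adam; early stopping
    monitors *training* accuracy with the given patience, and the parameters
    at the last strict improvement are restored (ties do not reset patience).

    Parameters
    ----------
    backbone : {"small_cnn", "paper_backbone"}
        Only ``small_cnn`` is runnable offline; see module docstring.
    embed_dim : int
        Embedding width of the trunk (64 for small_cnn; the real-cohort
        configuration uses 1024).
    hidden_dim : int or None
        Width of the first of the two fully connected head layers
        (default ``embed_dim // 2``).
    learning_rate, max_epochs, patience, batch_size, seed
        Optimization schedule; defaults follow the reference protocol
        (Adam, lr 2e-4, up to 150 epochs, patience 15).
    """

    def __init__(self, backbone="small_cnn", embed_dim=64, hidden_dim=None,
                 learning_rate=2e-4, max_epochs=150, patience=15,
                 batch_size=64, seed=0):
        self.backbone = backbone
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.seed = seed

    # -- construction ------------------------------------------------------
    def _build(self, rng: np.random.Generator):
        if self.backbone == "paper_backbone":
            raise ValueError(
                "backbone='paper_backbone' (ImageNet-pretrained truncated ResNet50, "
                "1024-dim embedding) requires pretrained weights that are not bundled "
                "with this package; use backbone='small_cnn'.")
        if self.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        ed = int(self.embed_dim)
        hd = int(self.hidden_dim) if self.hidden_dim is not None else max(ed // 2, 1)
        c1, c2 = max(ed // 4, 4), max(ed // 2, 8)
        feature = nn.Sequential(
            nn.Conv2d(3, c1, 3, stride=2, padding="valid", rng=rng),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Conv2d(c1, c2, 3, stride=1, padding="same", rng=rng),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Conv2d(c2, ed, 3, stride=1, padding="same", rng=rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
        )
        head = nn.Sequential(nn.Dense(ed, hd, rng=rng), nn.ReLU(), nn.Dense(hd, 1, rng=rng))
        return feature, head

    @staticmethod
    def _normalize(X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected image batch (N, H, W, 3), got shape {x.shape}")
        return (x / 255.0 - _PIXEL_MEAN) / _PIXEL_SCALE

    # -- training ----------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64).ravel()
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training patches must contain both classes "
                             "(binary cross-entropy is degenerate otherwise)")
        if not np.all(np.isin(classes, [0, 1])):
            raise ValueError("labels must be binary 0/1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        X = self._normalize(X)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")

        rng = np.random.default_rng(self.seed)
        feature, head = self._build(rng)
        params = list(feature.param_items()) + list(head.param_items())
        opt = nn.Adam(params, lr=self.learning_rate)

        n = len(X)
        best_acc, best_loss, best_state, since = -np.inf, np.inf, None, 0
        history = []
        for epoch in range(int(self.max_epochs)):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                feature.zero_grad(); head.zero_grad()
                emb = feature.forward(xb)
                logits = head.forward(emb)[:, 0]
                loss, dlogit = nn.bce_with_logits(logits, yb)
                head_grad = head.backward(dlogit[:, None].astype(np.float32))
                feature.backward(head_grad)
                opt.step()
                losses.append(loss)
                correct += int(np.sum((logits > 0) == (yb > 0.5)))
            acc = correct / n
            epoch_loss = float(np.mean(losses))
            history.append({"epoch": epoch, "loss": epoch_loss, "accuracy": acc})
            # strict accuracy improvement resets patience; among accuracy ties
            # the checkpoint moves to the lower-loss model without resetting it
            if acc > best_acc:
                best_acc, best_loss, since = acc, epoch_loss, 0
                best_state = (feature.state_dict(), head.state_dict())
            else:
                if acc == best_acc and epoch_loss < best_loss:
                    best_loss = epoch_loss
                    best_state = (feature.state_dict(), head.state_dict())
                since += 1
            if since >= self.patience:
                break
        feature.load_state_dict(best_state[0])
        head.load_state_dict(best_state[1])

        self.classes_ = np.array([0, 1])
        self.feature_net_ = feature
        self.head_net_ = head
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = len(history)
        self.best_accuracy_ = float(best_acc)
        return self

    def _check_fitted(self):
        if not hasattr(self, "feature_net_"):
            raise ValueError("PatchScorer is not fitted yet; call fit first")

    def _batched(self, X, fn):
        outs = []
        for start in range(0, len(X), self.batch_size):
            outs.append(fn(X[start:start + self.batch_size]))
        return np.concatenate(outs, axis=0)

    # -- inference ---------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Embed patches with the feature trunk: (N, H, W, 3) -> (N, embed_dim)."""
        self._check_fitted()
        X = self._normalize(X)
        return self._batched(X, lambda xb: self.feature_net_.forward(xb, train=False))

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._normalize(X)

        def fn(xb):
            return self.head_net_.forward(self.feature_net_.forward(xb, train=False),
                                          train=False)[:, 0]
        return self._batched(X, fn)

    def predict_proba(self, X) -> np.ndarray:
        p1 = nn.sigmoid(self.decision_function(X).astype(np.float64))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def embed_from_logit_input(self, emb: np.ndarray) -> np.ndarray:
        """Apply only the head to precomputed embeddings (utility)."""
        self._check_fitted()
        return self.head_net_.forward(np.asarray(emb, dtype=np.float32), train=False)[:, 0]

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file archive: parameter arrays plus an embedded JSON config."""
        self._check_fitted()
        state = {}
        for k, v in self.feature_net_.state_dict().items():
            state[f"feature.{k}"] = v
        for k, v in self.head_net_.state_dict().items():
            state[f"head.{k}"] = v
        config = json.dumps(self.get_params())
        np.savez(path, __config__=np.frombuffer(config.encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "PatchScorer":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            model = cls(**config)
            rng = np.random.default_rng(model.seed)
            feature, head = model._build(rng)
            feature.load_state_dict({k[len("feature."):]: data[k] for k in data.files
                                     if k.startswith("feature.")})
            head.load_state_dict({k[len("head."):]: data[k] for k in data.files
                                  if k.startswith("head.")})
        model.feature_net_, model.head_net_ = feature, head
        model.classes_ = np.array([0, 1])
        return model


def score_slide(model: PatchScorer, slide, manifest: pd.DataFrame) -> pd.DataFrame:
    """Score every ROI patch of one slide: probability and DS per patch.

    ``manifest`` must contain rows for the slide; rows belonging to other
    slides are ignored.  Output order matches the manifest's row-major patch
    order and is independent of batching.
    """
    sub = manifest[manifest["slide_id"] == slide.slide_id]
    if len(sub) == 0:
        raise ValueError(f"manifest has no patches for slide {slide.slide_id!r}")
    images = load_patch_images([slide], sub)
    prob = model.predict_proba(images)[:, 1]
    out = sub[["slide_id", "x", "y", "size_px"]].copy().reset_index(drop=True)
    out["probability"] = prob
    out["ds"] = discrimination_score(prob)
    return out
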