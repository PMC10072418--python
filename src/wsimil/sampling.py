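"""Discriminative patch sampling: rank by DS, keep the top K, embed a bag.

Ranking is *per slide*: the DS distribution differs between slides, so a
global threshold would under- or over-sample individual slides; taking each
slide's top-K patches sidesteps that.  Ties in DS are broken by row-major
patch coordinate order so the selection is deterministic across runs and
platforms.  The K selected patches are embedded by the scorer's feature trunk
and stored as a K x D bag; bags are persisted to HDF5 so the MIL stage never
re-touches pixels (this is the mechanism that makes slide-level training and
inference cheap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .scorer import PatchScorer, load_patch_images
from .tiling import PatchRef, SlideRecord

__all__ = ["Bag", "rank_patches", "select_top_k", "embed_bag", "build_bag",
           "save_bags", "load_bags", "BAGS_FORMAT_VERSION"]

logger = logging.getLogger(__name__)

BAGS_FORMAT_VERSION = 1


@dataclass
class Bag:
    """One slide's instances: K x D embedding matrix plus aligned patch refs."""

    slide_id: str
    instances: np.ndarray
    refs: list[PatchRef]
    label: int

    def __post_init__(self):
        if len(self.refs) != self.instances.shape[0]:
            raise ValueError("refs length must equal instance-matrix row count")


def rank_patches(scored) -> np.ndarray:
    """Indices of patches ordered by DS descending.

    ``scored`` is either a DataFrame with columns ``ds``, ``x``, ``y`` (ties
    broken by row-major coordinates) or a plain DS array (ties broken by
    position, which equals row-major order for manifests built by tiling).
    """
    if isinstance(scored, pd.DataFrame):
        if len(scored) == 0:
            raise ValueError("cannot rank an empty patch list")
        ds = scored["ds"].to_numpy(dtype=np.float64)
        # lexsort: last key is primary
        return np.lexsort((scored["x"].to_numpy(), scored["y"].to_numpy(), -ds))
    ds = np.asarray(scored, dtype=np.float64)
    if ds.size == 0:
        raise ValueError("cannot rank an empty patch list")
    return np.argsort(-ds, kind="stable")


def select_top_k(ranked: np.ndarray, k: int) -> np.ndarray:
    """First ``min(k, n)`` entries of a ranking; logs when a slide falls short."""
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    ranked = np.asarray(ranked)
    if k < len(ranked):
        return ranked[:k]
    if k > len(ranked):
        logger.info("requested K=%d but only %d patches available; keeping all",
                    k, len(ranked))
    return ranked.copy()


def embed_bag(model: PatchScorer, slide: SlideRecord, selected: pd.DataFrame) -> Bag:
    """Embed the selected patches (in ranking order) into a bag.

    ``selected`` rows must already be in DS-ranking order; row k of the bag is
    the feature-trunk embedding of patch k.
    """
    if len(selected) == 0:
        raise ValueError("cannot embed an empty selection")
    images = load_patch_images([slide], selected)
    instances = model.transform(images)
    refs = [PatchRef(slide.slide_id, int(r.y), int(r.x), int(r.size_px))
            for r in selected.itertuples()]
    return Bag(slide_id=slide.slide_id, instances=instances, refs=refs,
               label=int(slide.label))


def build_bag(model: PatchScorer, slide: SlideRecord, scored: pd.DataFrame,
              k: int) -> Bag:
    """Rank one slide's scored patches, keep the top K, embed them."""
    order = rank_patches(scored)
    sel = select_top_k(order, k)
    return embed_bag(model, slide, scored.iloc[sel])


def save_bags(bags: list[Bag], path, k: int | None = None) -> None:
    """Persist bags to HDF5, one group per slide.

    Layout (version 1): file attrs ``format_version``, ``embed_dim``, ``k``;
    per-slide group with datasets ``instances`` (K x D float32), ``x``, ``y``,
    ``size_px`` (int32) and attr ``label``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = BAGS_FORMAT_VERSION
        if bags:
            f.attrs["embed_dim"] = bags[0].instances.shape[1]
        if k is not None:
            f.attrs["k"] = k
        for bag in bags:
            g = f.create_group(bag.slide_id)
            g.create_dataset("instances", data=bag.instances.astype(np.float32))
            g.create_dataset("x", data=np.array([r.x for r in bag.refs], dtype=np.int32))
            g.create_dataset("y", data=np.array([r.y for r in bag.refs], dtype=np.int32))
            g.create_dataset("size_px",
                             data=np.array([r.size_px for r in bag.refs], dtype=np.int32))
            g.attrs["label"] = bag.label


def load_bags(path) -> list[Bag]:
    """Load bags from HDF5, ordered by slide id for determinism."""
    out = []
    with h5py.File(path, "r") as f:
        for slide_id in sorted(f.keys()):
            g = f[slide_id]
            refs = [PatchRef(slide_id, int(y), int(x), int(s))
                    for x, y, s in zip(g["x"][...], g["y"][...], g["size_px"][...])]
            out.append(Bag(slide_id=slide_id, instances=g["instances"][...],
                           refs=refs, label=int(g.attrs["label"])))
    return out
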