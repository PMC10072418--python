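"""Shared fixtures: small synthetic cohorts and helper bag factories."""

from __future__ import annotations

import numpy as np
import pytest

from wsimil import CohortConfig, generate_cohort
from wsimil.sampling import Bag
from wsimil.tiling import PatchRef


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """4 + 4 slides, 16 patches per slide (4x4 grid), 32 px patches."""
    root = tmp_path_factory.mktemp("tiny_cohort")
    config = CohortConfig(n_slides_per_class=4, patches_per_slide=16,
                          patch_size_px=32, positive_instance_fraction=0.4,
                          nondiscriminative_fraction=0.2, seed=5)
    return generate_cohort(config, root)


def make_gaussian_bags(n_per_class: int, k: int, d: int, shift: float = 3.0,
                       positive_fraction: float = 0.4, seed: int = 0) -> list[Bag]:
    """Separable MIL toy data: positive bags contain shifted-mean instances."""
    rng = np.random.default_rng(seed)
    bags = []
    for label in (0, 1):
        for i in range(n_per_class):
            X = rng.normal(size=(k, d))
            if label == 1:
                n_pos = max(1, int(round(positive_fraction * k)))
                X[:n_pos, 0] += shift
            refs = [PatchRef(f"bag{label}_{i}", r * 10, 0, 10) for r in range(k)]
            bags.append(Bag(slide_id=f"bag{label}_{i}", instances=X, refs=refs,
                            label=label))
    return bags


@pytest.fixture()
def gaussian_bags():
    return make_gaussian_bags(n_per_class=12, k=8, d=6, seed=3)
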