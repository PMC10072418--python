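"""Synthetic weakly-labeled slide cohorts.

The generator emulates the statistical structure the two-stage pipeline
assumes, without attempting photorealistic histology.  A slide is a mosaic of
square patches on a regular grid; the ROI (the annotated "tumor region")
covers the inner cells and is surrounded by a margin of background cells.
Patches come in four kinds:

* ``discriminative_positive`` — dense disc-shaped "stained" blobs, emulating a
  high density of proliferating cells; found only in positive (high-risk)
  slides,
* ``discriminative_negative`` — sparse blobs, found in slides of both classes,
* ``nondiscriminative`` — blob count drawn from a mixture straddling both
  class densities, so the patch carries no label information,
* ``background`` — bright, blob-free tissue-free area outside the ROI.

Positive slides therefore contain a mixture of dense and sparse patches while
negative slides contain only sparse/ambiguous ones — the standard multiple
instance learning assumption (positive bags contain positive instances,
negative bags none).

Reproducibility: one root seed; each slide draws from its own child stream
``SeedSequence([seed, slide_index])`` where ``slide_index`` is the slide's
position in the class-0-first, index-ordered slide list, so a slide's pixels
do not depend on generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import box, mapping
from shapely.ops import unary_union

__all__ = [
    "KIND_POSITIVE",
    "KIND_NEGATIVE",
    "KIND_NONDISCRIMINATIVE",
    "KIND_BACKGROUND",
    "PATCH_KINDS",
    "PatchSpec",
    "CohortConfig",
    "SyntheticCohort",
    "sample_blob_count",
    "generate_patch",
    "generate_cohort",
]

KIND_POSITIVE = "discriminative_positive"
KIND_NEGATIVE = "discriminative_negative"
KIND_NONDISCRIMINATIVE = "nondiscriminative"
KIND_BACKGROUND = "background"
PATCH_KINDS = (KIND_POSITIVE, KIND_NEGATIVE, KIND_NONDISCRIMINATIVE, KIND_BACKGROUND)

# Blob ("stained proliferating cell") colour and canvas tones, RGB uint8 scale.
_BLOB_COLOR = np.array([125.0, 78.0, 40.0])        # brown-like hue
_TISSUE_COLOR = np.array([214.0, 172.0, 190.0])    # pale pink tissue
_BACKGROUND_COLOR = np.array([242.0, 240.0, 238.0])


@dataclass(frozen=True)
class PatchSpec:
    """Recipe for one synthetic patch.

    ``blob_density`` is the expected blob count per patch.  For
    ``nondiscriminative`` patches the rate itself is drawn uniformly between
    ``alt_blob_density`` and ``blob_density`` — a continuous mixture of
    Poissons whose support straddles both class densities — so the patch's
    appearance is intermediate and carries little label information (the
    scorer cannot push it confidently to either class).  For ``background``
    the count is always zero.
    """

    kind: str
    size_px: int = 64
    blob_density: float = 8.0
    noise_sd: float = 6.0
    alt_blob_density: float | None = None

    def __post_init__(self):
        if self.kind not in PATCH_KINDS:
            raise ValueError(f"unknown patch kind {self.kind!r}; expected one of {PATCH_KINDS}")
        if self.size_px <= 0:
            raise ValueError(f"size_px must be positive, got {self.size_px}")
        if self.blob_density < 0 or self.noise_sd < 0:
            raise ValueError("blob_density and noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``positive_instance_fraction`` is the fraction of a positive slide's ROI
    patches that are discriminative_positive; negative slides never contain
    any.  Blob densities default to 8 (positive) vs 2 (negative) expected
    blobs per patch — the density gap is a simulator parameter, not a claim
    about biology.
    """

    n_slides_per_class: int = 20
    patches_per_slide: int = 64
    positive_instance_fraction: float = 0.3
    nondiscriminative_fraction: float = 0.2
    background_margin_patches: int = 1
    patch_size_px: int = 64
    pos_blob_density: float = 8.0
    neg_blob_density: float = 2.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_slides_per_class < 1 or self.patches_per_slide < 1:
            raise ValueError("n_slides_per_class and patches_per_slide must be >= 1")
        if not (0.0 < self.positive_instance_fraction <= 1.0):
            raise ValueError("positive_instance_fraction must lie in (0, 1]")
        if not (0.0 <= self.nondiscriminative_fraction < 1.0):
            raise ValueError("nondiscriminative_fraction must lie in [0, 1)")
        if self.positive_instance_fraction + self.nondiscriminative_fraction > 1.0 + 1e-12:
            raise ValueError("positive_instance_fraction + nondiscriminative_fraction must be <= 1")
        if self.background_margin_patches < 0:
            raise ValueError("background_margin_patches must be >= 0")
        if self.pos_blob_density <= self.neg_blob_density:
            raise ValueError("pos_blob_density must exceed neg_blob_density")


@dataclass
class SyntheticCohort:
    """Handle to a cohort written on disk."""

    root: Path
    labels: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig = field(repr=False, default=None)

    @property
    def image_dir(self) -> Path:
        return self.root / "images"

    @property
    def annotation_dir(self) -> Path:
        return self.root / "annotations"

    def image_path(self, slide_id: str) -> Path:
        for ext in (".png", ".tif"):
            p = self.image_dir / f"{slide_id}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(f"no image for slide {slide_id!r} under {self.image_dir}")


def sample_blob_count(spec: PatchSpec, rng: np.random.Generator) -> int:
    """Draw the blob count for one patch according to its kind."""
    if spec.kind == KIND_BACKGROUND:
        return 0
    if spec.kind == KIND_NONDISCRIMINATIVE:
        alt = spec.alt_blob_density
        if alt is None:
            alt = 0.25 * spec.blob_density
        lo, hi = min(alt, spec.blob_density), max(alt, spec.blob_density)
        return int(rng.poisson(rng.uniform(lo, hi)))
    return int(rng.poisson(spec.blob_density))


def _paint_blob(img: np.ndarray, cx: float, cy: float, radius: float) -> None:
    """Alpha-composite one anti-aliased disc onto ``img`` (H, W, 3 float)."""
    size = img.shape[0]
    x0 = max(int(np.floor(cx - radius - 1)), 0)
    x1 = min(int(np.ceil(cx + radius + 2)), size)
    y0 = max(int(np.floor(cy - radius - 1)), 0)
    y1 = min(int(np.ceil(cy + radius + 2)), size)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)[..., None]
    img[y0:y1, x0:x1, :] = img[y0:y1, x0:x1, :] * (1 - alpha) + _BLOB_COLOR * alpha


def generate_patch(spec: PatchSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one patch as a ``(size, size, 3)`` uint8 array.

    Tissue patches get a textured pale-pink canvas; blobs are anti-aliased
    brown discs with radius uniform in 5–10 % of the patch side.  Background
    patches are a uniform bright canvas.  Gaussian pixel noise of sd
    ``noise_sd`` is added everywhere.
    """
    s = spec.size_px
    if spec.kind == KIND_BACKGROUND:
        img = np.broadcast_to(_BACKGROUND_COLOR, (s, s, 3)).astype(np.float64).copy()
    else:
        img = np.broadcast_to(_TISSUE_COLOR, (s, s, 3)).astype(np.float64).copy()
        # coarse low-frequency texture so the canvas is not flat
        coarse = rng.normal(0.0, 10.0, size=(s // 8 + 2, s // 8 + 2))
        texture = np.kron(coarse, np.ones((8, 8)))[:s, :s]
        img += texture[..., None]
        n_blobs = sample_blob_count(spec, rng)
        for _ in range(n_blobs):
            cx, cy = rng.uniform(0, s, size=2)
            radius = rng.uniform(0.05, 0.10) * s
            _paint_blob(img, cx, cy, radius)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _grid_shape(patches_per_slide: int) -> tuple[int, int]:
    cols = int(np.ceil(np.sqrt(patches_per_slide)))
    rows = int(np.ceil(patches_per_slide / cols))
    return rows, cols


def _roi_polygon(config: CohortConfig) -> "shapely.geometry.Polygon":
    """ROI as a rectilinear polygon covering the first ``m`` grid cells."""
    m = config.patches_per_slide
    rows, cols = _grid_shape(m)
    b = config.background_margin_patches
    ps = config.patch_size_px
    full_rows, rem = divmod(m, cols)
    parts = []
    if full_rows:
        parts.append(box(b * ps, b * ps, (b + cols) * ps, (b + full_rows) * ps))
    if rem:
        parts.append(box(b * ps, (b + full_rows) * ps, (b + rem) * ps, (b + full_rows + 1) * ps))
    return unary_union(parts)


def _slide_kinds(config: CohortConfig, label: int, rng: np.random.Generator) -> list[str]:
    m = config.patches_per_slide
    n_nd = int(round(config.nondiscriminative_fraction * m))
    if label == 1:
        n_pos = int(round(config.positive_instance_fraction * m))
        n_nd = min(n_nd, m - n_pos)
    else:
        n_pos = 0
    kinds = ([KIND_POSITIVE] * n_pos + [KIND_NONDISCRIMINATIVE] * n_nd
             + [KIND_NEGATIVE] * (m - n_pos - n_nd))
    rng.shuffle(kinds)
    return kinds


def _patch_spec_for(kind: str, config: CohortConfig) -> PatchSpec:
    density = {KIND_POSITIVE: config.pos_blob_density,
               KIND_NEGATIVE: config.neg_blob_density,
               KIND_NONDISCRIMINATIVE: config.pos_blob_density,
               KIND_BACKGROUND: 0.0}[kind]
    return PatchSpec(kind=kind, size_px=config.patch_size_px, blob_density=density,
                     noise_sd=config.noise_sd,
                     alt_blob_density=config.neg_blob_density if kind == KIND_NONDISCRIMINATIVE else None)


def render_slide(config: CohortConfig, label: int, slide_index: int):
    """Render one slide mosaic deterministically from its child stream.

    Returns ``(image, truth_rows, covariates)`` where ``truth_rows`` is a list
    of ``(x, y, kind)`` pixel-origin records for every grid cell and
    ``covariates`` is a dict with synthetic ``odx_score`` and ``grade``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, slide_index]))
    # covariates first, then layout, then pixels — fixed draw order
    if label == 1:
        odx = float(np.round(rng.uniform(25.0, 60.0), 1))
        grade = int(rng.choice([1, 2, 3], p=[0.05, 0.45, 0.50]))
    else:
        odx = float(np.round(rng.uniform(2.0, 24.9), 1))
        grade = int(rng.choice([1, 2, 3], p=[0.45, 0.45, 0.10]))
    rows, cols = _grid_shape(config.patches_per_slide)
    b = config.background_margin_patches
    ps = config.patch_size_px
    h = (rows + 2 * b) * ps
    w = (cols + 2 * b) * ps
    image = np.empty((h, w, 3), dtype=np.uint8)
    roi_kinds = _slide_kinds(config, label, rng)
    truth_rows = []
    cell = 0
    for r in range(rows + 2 * b):
        for c in range(cols + 2 * b):
            in_roi = (b <= r < b + rows) and (b <= c < b + cols)
            if in_roi:
                idx = (r - b) * cols + (c - b)
                kind = roi_kinds[idx] if idx < config.patches_per_slide else KIND_BACKGROUND
            else:
                kind = KIND_BACKGROUND
            spec = _patch_spec_for(kind, config)
            patch = generate_patch(spec, rng)
            image[r * ps:(r + 1) * ps, c * ps:(c + 1) * ps, :] = patch
            truth_rows.append((c * ps, r * ps, kind))
            cell += 1
    return image, truth_rows, {"odx_score": odx, "grade": grade}


def generate_cohort(config: CohortConfig, out_dir: str | Path,
                    image_format: str = "png") -> SyntheticCohort:
    """Write a full cohort (images, GeoJSON ROIs, label CSV, truth sidecar).

    The sidecar ``patch_truth.csv`` holds ground-truth per-patch kinds for
    oracle tests only; the analysis pipeline never reads it (supervision stays
    weak).  Config validation happens before any file is written.
    """
    if image_format not in ("png", "tiff"):
        raise ValueError(f"image_format must be 'png' or 'tiff', got {image_format!r}")
    # config invariants are checked in CohortConfig.__post_init__; re-validate
    # here in case a caller built the dataclass via __new__/replace tricks
    CohortConfig(**{f: getattr(config, f) for f in config.__dataclass_fields__})

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    roi = _roi_polygon(config)
    label_rows = []
    truth_rows = []
    slide_index = 0
    for label in (0, 1):
        for i in range(config.n_slides_per_class):
            slide_id = f"slide_{'neg' if label == 0 else 'pos'}_{i:03d}"
            image, cells, cov = render_slide(config, label, slide_index)
            ext = ".png" if image_format == "png" else ".tif"
            img_path = out_dir / "images" / f"{slide_id}{ext}"
            if image_format == "png":
                iio.imwrite(img_path, image)
            else:
                tifffile.imwrite(img_path, image)
            feature = {
                "type": "Feature",
                "properties": {"slide_id": slide_id},
                "geometry": mapping(roi),
            }
            geo = {"type": "FeatureCollection", "features": [feature]}
            (out_dir / "annotations" / f"{slide_id}.geojson").write_text(
                json.dumps(geo, indent=None, sort_keys=True))
            label_rows.append({"slide_id": slide_id, "label": label, **cov})
            truth_rows.extend({"slide_id": slide_id, "x": x, "y": y, "kind": kind}
                              for x, y, kind in cells)
            slide_index += 1

    labels = pd.DataFrame(label_rows)
    truth = pd.DataFrame(truth_rows)
    labels.to_csv(out_dir / "labels.csv", index=False)
    truth.to_csv(out_dir / "patch_truth.csv", index=False)
    return SyntheticCohort(root=out_dir, labels=labels, truth=truth, config=config)


def load_cohort(root: str | Path) -> SyntheticCohort:
    """Re-open a cohort directory written by :func:`generate_cohort`."""
    root = Path(root)
    labels = pd.read_csv(root / "labels.csv")
    truth_path = root / "patch_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return SyntheticCohort(root=root, labels=labels, truth=truth)
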