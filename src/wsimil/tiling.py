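"""Slide tiling: turn an image plus ROI polygons into fixed-size patches.

Coordinates are 0-based pixels, origin at the top-left, with half-open patch
windows ``[x, x+size) x [y, y+size)``.  A grid patch belongs to the ROI iff
its *center point* lies inside at least one annotation polygon; everything
else is background and is excluded from the analysis universe.  The center
rule is a package choice (full containment is stricter near boundaries) and
is deliberately the only inclusion rule implemented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely import contains_xy
from shapely.geometry import Polygon, shape

__all__ = ["SlideRecord", "PatchRef", "tile_roi", "read_patch",
           "load_slide_records", "build_manifest", "read_geojson_polygons"]


@dataclass
class SlideRecord:
    """One slide: image source, ROI polygons, binary risk label.

    ``label`` follows the recurrence-score cutoff convention (score < 25 ->
    0 = low risk, >= 25 -> 1 = high risk).  The pixel array is cached after
    the first read.
    """

    slide_id: str
    image_path: Path
    roi_polygons: list[Polygon]
    label: int
    stain: str = "synthetic"
    _image: np.ndarray | None = field(default=None, repr=False, compare=False)

    def image(self) -> np.ndarray:
        if self._image is None:
            path = Path(self.image_path)
            if path.suffix.lower() in (".tif", ".tiff"):
                self._image = tifffile.imread(path)
            else:
                self._image = iio.imread(path)
        return self._image


@dataclass(frozen=True, order=True)
class PatchRef:
    """Origin and size of one patch window on a slide (sorted row-major)."""

    slide_id: str
    y: int
    x: int
    size_px: int


def read_geojson_polygons(path: str | Path) -> list[Polygon]:
    """Load all polygons of a GeoJSON FeatureCollection (pixel coordinates)."""
    doc = json.loads(Path(path).read_text())
    polys: list[Polygon] = []
    for feature in doc.get("features", []):
        geom = shape(feature["geometry"])
        if geom.geom_type == "Polygon":
            polys.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
    return polys


def tile_roi(slide: SlideRecord, patch_size: int, stride: int | None = None) -> list[PatchRef]:
    """Enumerate all grid patches whose centers fall inside an ROI polygon.

    The grid starts at (0, 0) and advances by ``stride`` (default:
    ``patch_size``, i.e. non-overlapping).  Output order is row-major
    (y outer, x inner) and deterministic.  An empty polygon list is an error;
    an ROI smaller than one patch simply yields an empty list.
    """
    if patch_size <= 0:
        raise ValueError(f"patch_size must be positive, got {patch_size}")
    stride = patch_size if stride is None else stride
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    if not slide.roi_polygons:
        raise ValueError(f"slide {slide.slide_id!r} has no ROI polygons")
    img = slide.image()
    h, w = img.shape[:2]
    xs = np.arange(0, w - patch_size + 1, stride)
    ys = np.arange(0, h - patch_size + 1, stride)
    if len(xs) == 0 or len(ys) == 0:
        return []
    gx, gy = np.meshgrid(xs, ys)
    cx = gx.ravel() + patch_size / 2.0
    cy = gy.ravel() + patch_size / 2.0
    inside = np.zeros(cx.shape, dtype=bool)
    for poly in slide.roi_polygons:
        inside |= contains_xy(poly, cx, cy)
    return [PatchRef(slide.slide_id, int(y), int(x), patch_size)
            for x, y, ok in zip(gx.ravel(), gy.ravel(), inside) if ok]


def read_patch(slide: SlideRecord, ref: PatchRef) -> np.ndarray:
    """Return the exact pixel window of ``ref`` (no resampling)."""
    if ref.slide_id != slide.slide_id:
        raise ValueError(f"ref belongs to slide {ref.slide_id!r}, not {slide.slide_id!r}")
    img = slide.image()
    h, w = img.shape[:2]
    if ref.x < 0 or ref.y < 0 or ref.x + ref.size_px > w or ref.y + ref.size_px > h:
        raise ValueError(f"patch {ref} exceeds image bounds {w}x{h}")
    return img[ref.y:ref.y + ref.size_px, ref.x:ref.x + ref.size_px]


def load_slide_records(cohort_root: str | Path, stain: str = "synthetic") -> list[SlideRecord]:
    """Build SlideRecords from a cohort directory (labels.csv + annotations/)."""
    root = Path(cohort_root)
    labels = pd.read_csv(root / "labels.csv")
    records = []
    for row in labels.itertuples():
        img_path = None
        for ext in (".png", ".tif", ".tiff"):
            cand = root / "images" / f"{row.slide_id}{ext}"
            if cand.exists():
                img_path = cand
                break
        if img_path is None:
            raise FileNotFoundError(f"no image for slide {row.slide_id!r}")
        polys = read_geojson_polygons(root / "annotations" / f"{row.slide_id}.geojson")
        records.append(SlideRecord(slide_id=row.slide_id, image_path=img_path,
                                   roi_polygons=polys, label=int(row.label), stain=stain))
    return records


def build_manifest(slides: list[SlideRecord], patch_size: int,
                   stride: int | None = None) -> pd.DataFrame:
    """Tile every slide and collect the patch universe as a manifest table."""
    rows = []
    for slide in slides:
        for ref in tile_roi(slide, patch_size, stride):
            rows.append({"slide_id": ref.slide_id, "x": ref.x, "y": ref.y,
                         "size_px": ref.size_px})
    return pd.DataFrame(rows, columns=["slide_id", "x", "y", "size_px"])
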