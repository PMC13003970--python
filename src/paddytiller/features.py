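"""The 12 tillering features and their [1, 2] normalization.

Per plant (or per plot sample) ten morphological features — total area,
perimeter, bounding-rectangle height/width, area/rectangle ratio,
rectangle aspect, box-counting fractal dimension, perimeter/area ratio,
convex-hull area, area/hull ratio — and two colour features — green value
and green ratio — quantify canopy size, shape complexity and nutritional
status, all of which track tillering vigour.

Conventions that matter for the regression scales:

* perimeter is the count of boundary pixels (8-neighbour rule), not a
  polygonal arc length;
* green value divides the summed G component of green pixels by the total
  pixel count of the analysis tile, so it is diluted by tile area;
* the area/rectangle coverage ratio is capped at 1 (the rectangle is fit
  to pixel centers, so raw coverage can slightly exceed it);
* features are normalized per column to [1, 2] by x' = 1 + (x−min)/(max−min),
  removing unit/scale imbalance before model fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .image_io import RgbImage
from .morphology import PlantRegion, convex_hull, min_area_rect

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "BoxCountSeries",
    "extract_features",
    "extract_color",
    "fractal_dimension",
    "box_count_series",
    "normalize_features",
    "FeatureScaler",
    "aggregate_plot_sample",
]

FEATURE_NAMES = (
    "total_area",
    "perimeter",
    "rect_height",
    "rect_width",
    "area_rect_ratio",
    "rect_aspect",
    "fractal_dim",
    "perim_area_ratio",
    "hull_area",
    "area_hull_ratio",
    "green_value",
    "green_ratio",
)


@dataclass
class FeatureVector:
    total_area: float
    perimeter: float
    rect_height: float
    rect_width: float
    area_rect_ratio: float
    rect_aspect: float
    fractal_dim: float
    perim_area_ratio: float
    hull_area: float
    area_hull_ratio: float
    green_value: float
    green_ratio: float

    def __post_init__(self) -> None:
        if self.total_area <= 0:
            raise ValueError("total_area must be positive")
        if not 0.0 <= self.green_ratio <= 1.0:
            raise ValueError("green_ratio must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass
class BoxCountSeries:
    """Box sizes ε and occupied-box counts N(ε) on a fixed grid."""

    epsilons: np.ndarray
    counts: np.ndarray


def box_count_series(mask_patch: np.ndarray) -> BoxCountSeries:
    """Occupied ε×ε box counts for ε = 2, 4, …, M/4 on a grid anchored at
    the patch origin; the patch is zero-padded to the next power-of-two
    square M ≥ 8."""
    patch = np.asarray(mask_patch).astype(bool)
    if patch.sum() == 0:
        raise ValueError("empty patch")
    m = 8
    while m < max(patch.shape):
        m *= 2
    canvas = np.zeros((m, m), dtype=bool)
    canvas[: patch.shape[0], : patch.shape[1]] = patch
    eps, counts = [], []
    e = 2
    while e <= m // 4:
        n = canvas.reshape(m // e, e, m // e, e).any(axis=(1, 3)).sum()
        eps.append(e)
        counts.append(int(n))
        e *= 2
    return BoxCountSeries(np.array(eps), np.array(counts))


def fractal_dimension(mask_patch: np.ndarray) -> float:
    """Box-counting fractal dimension: least-squares slope of log N(ε)
    against log(1/ε).

    Space-filling regions approach 2, curve-like regions 1.  Patches
    smaller than 8 px in either direction are below the sampling floor of
    the box series; they return the curve-limit value 1.0.
    """
    patch = np.asarray(mask_patch).astype(bool)
    if min(patch.shape) < 8:
        return 1.0
    series = box_count_series(patch)
    x = np.log(1.0 / series.epsilons)
    y = np.log(series.counts.astype(float))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def extract_color(
    region: PlantRegion, img: RgbImage | np.ndarray, tile_px: int | None = None
) -> dict[str, float]:
    """Green value and green ratio of a plant within its analysis tile.

    Green pixels are region pixels with G strictly dominant (G > R and
    G > B).  ``tile_px`` is the pixel count of the analysis tile the plant
    was sampled from (defaults to the whole image).
    """
    px = np.asarray(img.pixels if isinstance(img, RgbImage) else img).astype(int)
    total = tile_px if tile_px is not None else px.shape[0] * px.shape[1]
    rows, cols = region.pixel_coords[:, 0], region.pixel_coords[:, 1]
    r, g, b = px[rows, cols, 0], px[rows, cols, 1], px[rows, cols, 2]
    greenish = (g > r) & (g > b)
    return {
        "green_value": float(g[greenish].sum()) / total,
        "green_ratio": float(greenish.sum()) / total,
    }


def extract_features(
    region: PlantRegion, img: RgbImage | np.ndarray, tile_px: int | None = None
) -> FeatureVector:
    """All 12 tillering features of one plant region."""
    if region.area_px == 0:
        raise ValueError("empty region")
    area = float(region.area_px)
    perimeter = float(len(region.contour))
    rect = min_area_rect(region)
    rect_w = max(rect.width_px, 1.0)
    rect_h = max(rect.height_px, 1.0)
    _, hull_area = convex_hull(region)

    coords = region.pixel_coords
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    patch = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    patch[coords[:, 0] - r0, coords[:, 1] - c0] = True

    color = extract_color(region, img, tile_px)
    return FeatureVector(
        total_area=area,
        perimeter=perimeter,
        rect_height=rect_h,
        rect_width=rect_w,
        area_rect_ratio=min(area / (rect_w * rect_h), 1.0),
        rect_aspect=rect_w / rect_h,
        fractal_dim=fractal_dimension(patch),
        perim_area_ratio=perimeter / area,
        hull_area=hull_area,
        area_hull_ratio=min(area / hull_area, 1.0) if hull_area > 0 else 1.0,
        green_value=color["green_value"],
        green_ratio=color["green_ratio"],
    )


class FeatureScaler:
    """Per-column affine map onto [1, 2], refit-free for new data.

    x' = 1 + (x − min)/(max − min); constant columns map to 1; values
    outside the training range clip into [1, 2].
    """

    def __init__(self, mins: pd.Series, maxs: pd.Series):
        self.mins = mins
        self.maxs = maxs

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.mins.index:
            span = self.maxs[col] - self.mins[col]
            if span == 0:
                out[col] = 1.0
            else:
                out[col] = (1.0 + (table[col] - self.mins[col]) / span).clip(1.0, 2.0)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {c: [float(self.mins[c]), float(self.maxs[c])] for c in self.mins.index}
        )

    @classmethod
    def from_json(cls, doc: str) -> "FeatureScaler":
        d = json.loads(doc)
        return cls(
            pd.Series({k: v[0] for k, v in d.items()}),
            pd.Series({k: v[1] for k, v in d.items()}),
        )


def normalize_features(
    table: pd.DataFrame | list[FeatureVector], columns: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, FeatureScaler]:
    """Normalize a feature table to [1, 2] per column; returns the scaled
    table and the fitted scaler (for reuse on held-out data)."""
    if not isinstance(table, pd.DataFrame):
        if len(table) == 0:
            raise ValueError("empty feature table")
        table = pd.DataFrame([fv.as_array() for fv in table], columns=list(FEATURE_NAMES))
    if len(table) == 0:
        raise ValueError("empty feature table")
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c in FEATURE_NAMES or np.issubdtype(table[c].dtype, np.number)
    ]
    scaler = FeatureScaler(table[cols].min(), table[cols].max())
    return scaler.transform(table), scaler


def aggregate_plot_sample(feature_vectors: list[FeatureVector]) -> FeatureVector:
    """Per-plot sample value: the mean feature vector of the sampled hills
    (field protocol samples four hills per breeding plot)."""
    if not feature_vectors:
        raise ValueError("no feature vectors to aggregate")
    arr = np.mean([fv.as_array() for fv in feature_vectors], axis=0)
    return FeatureVector(**dict(zip(FEATURE_NAMES, arr)))
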