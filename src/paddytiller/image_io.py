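"""Raster I/O and polygon-annotation parsing.

The whole pipeline uses a two-class legend: pixel value 0 is background
(soil, water, reflections), pixel value 1 is rice plant.  Coordinates are
0-based, row-major, origin at the top-left corner; polygon vertices are
(x=column, y=row) pairs, the common annotation-JSON convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from PIL import Image

__all__ = [
    "RgbImage",
    "GrayImage",
    "BinaryMask",
    "read_image",
    "parse_polygon_labels",
    "write_mask_png",
    "read_mask_png",
]


@dataclass
class RgbImage:
    """An 8-bit colour raster, channel order R, G, B."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RgbImage expects H×W×3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("RgbImage must have H ≥ 1 and W ≥ 1")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("RgbImage intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """A single-channel 8-bit raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage expects H×W pixels, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("GrayImage intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Semantic label map: 0 = background, 1 = rice."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"BinaryMask expects H×W pixels, got shape {px.shape}")
        vals = np.unique(px)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"BinaryMask may only contain 0 and 1, found values {vals}")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_image(path: str | Path) -> RgbImage:
    """Read a PNG/JPEG/TIFF raster as an 8-bit RGB image.

    Grayscale inputs are replicated to three channels; 16-bit inputs are
    rescaled to [0, 255] by dividing by 257 (65535 → 255).
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = np.asarray(tifffile.imread(str(path)))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - decoder-specific messages
        raise OSError(f"cannot read image {path}: {exc}") from exc

    if arr.dtype == np.uint16:
        arr = np.round(arr / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]  # drop alpha
    else:
        raise OSError(f"cannot interpret image {path} with shape {arr.shape}")
    return RgbImage(arr)


def _rasterize_polygon(points: np.ndarray, height: int, width: int) -> np.ndarray:
    """Boolean raster of one polygon; a pixel belongs iff its center is
    covered by the polygon (boundary inclusive)."""
    poly = shapely.Polygon(points)
    if not poly.is_valid:
        # self-intersecting annotation: fall back to the even-odd repaired form
        poly = shapely.make_valid(poly)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(width - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(height - 1, int(np.ceil(maxy)))
    out = np.zeros((height, width), dtype=bool)
    if c1 < c0 or r1 < r0:
        return out
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(cols.ravel().astype(float), rows.ravel().astype(float))
    inside = shapely.covers(poly, pts).reshape(rows.shape)
    out[r0 : r1 + 1, c0 : c1 + 1] = inside
    return out


def parse_polygon_labels(json_doc: dict | str, height: int, width: int) -> BinaryMask:
    """Parse an annotation document (Labelme dialect) into a BinaryMask.

    ``json_doc`` is either the decoded document or a JSON string.  Shapes
    labelled ``"rice"`` are filled with 1; all other labels map to
    background.  Overlapping rice polygons union.  Polygons with fewer than
    three vertices are skipped with a warning.
    """
    if isinstance(json_doc, str):
        json_doc = json.loads(json_doc)
    mask = np.zeros((height, width), dtype=np.uint8)
    for shape in json_doc.get("shapes", []):
        if shape.get("label") != "rice":
            continue
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3:
            warnings.warn(
                f"skipping polygon with {0 if pts.ndim != 2 else pts.shape[0]} "
                "vertices (need ≥ 3)",
                stacklevel=2,
            )
            continue
        mask |= _rasterize_polygon(pts, height, width).astype(np.uint8)
    return BinaryMask(mask)


def write_mask_png(mask: BinaryMask, path: str | Path, visual: bool = False) -> None:
    """Write a mask as PNG: raw {0,1} values, or {0,255} when ``visual``."""
    if not isinstance(mask, BinaryMask):
        mask = BinaryMask(np.asarray(mask))
    px = mask.pixels * 255 if visual else mask.pixels
    Image.fromarray(px.astype(np.uint8), mode="L").save(Path(path))


def read_mask_png(path: str | Path) -> BinaryMask:
    """Read a mask PNG written by :func:`write_mask_png` (either mode)."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    vals = set(np.unique(arr))
    if vals <= {0, 1}:
        return BinaryMask(arr)
    if vals <= {0, 255}:
        return BinaryMask((arr > 0).astype(np.uint8))
    raise ValueError(f"file {path} is not a two-level mask (values {sorted(vals)})")
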