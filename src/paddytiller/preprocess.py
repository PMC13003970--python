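"""Canopy image enhancement: CLAHE contrast stretching and median denoising.

UAV images of early-tillering paddies are low-contrast (plant/background
boundaries wash out under flat illumination) and carry salt-and-pepper
noise.  Two conditioning steps address this:

* contrast-limited adaptive histogram equalization (CLAHE) over an 8×8 tile
  grid with clip limit 2.0 and bilinear blending of tile mappings, and
* 3×3 median filtering with symmetric (edge-duplicating mirror) padding.

Colour images are equalized on the luminance channel of a BT.601 RGB→YCbCr
transform so chroma — and hence greenness features downstream — is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import GrayImage, RgbImage

__all__ = ["ClaheParams", "MedianParams", "clahe", "median_filter"]


@dataclass
class ClaheParams:
    tile_rows: int = 8
    tile_cols: int = 8
    clip_limit: float = 2.0

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("CLAHE tile counts must be ≥ 1")
        if self.clip_limit < 1.0:
            raise ValueError("CLAHE clip limit must be ≥ 1.0")


@dataclass
class MedianParams:
    window: int = 3

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("median window must be odd and ≥ 3")


def _tile_lut(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Equalization lookup table of one tile with clipped histogram.

    The histogram is clipped at clip_limit × (mean bin count) and the excess
    mass redistributed uniformly in a single pass.
    """
    n = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    ceil = clip_limit * n / 256.0
    excess = np.maximum(hist - ceil, 0.0).sum()
    hist = np.minimum(hist, ceil) + excess / 256.0
    cdf = np.cumsum(hist) / n
    return np.round(255.0 * cdf)


def _clahe_gray(img: np.ndarray, params: ClaheParams) -> np.ndarray:
    h, w = img.shape
    tr = min(params.tile_rows, h)
    tc = min(params.tile_cols, w)
    row_edges = np.linspace(0, h, tr + 1).round().astype(int)
    col_edges = np.linspace(0, w, tc + 1).round().astype(int)
    luts = np.empty((tr, tc, 256))
    for i in range(tr):
        for j in range(tc):
            tile = img[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            luts[i, j] = _tile_lut(tile, params.clip_limit)

    # bilinear blend of the four surrounding tile mappings, anchored at tile
    # centers; outside the outer centers the nearest tile mapping extends
    rc = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    cc = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    def axis_weights(coords: np.ndarray, centers: np.ndarray):
        hi = np.searchsorted(centers, coords)
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        hi = np.clip(hi, 0, len(centers) - 1)
        span = centers[hi] - centers[lo]
        t = np.where(span > 0, (coords - centers[lo]) / np.where(span > 0, span, 1), 0.0)
        return lo, hi, np.clip(t, 0.0, 1.0)

    r_lo, r_hi, tv = axis_weights(np.arange(h, dtype=float), rc)
    c_lo, c_hi, tu = axis_weights(np.arange(w, dtype=float), cc)
    RL, CL = np.meshgrid(r_lo, c_lo, indexing="ij")
    RH, CH = np.meshgrid(r_hi, c_hi, indexing="ij")
    TV, TU = np.meshgrid(tv, tu, indexing="ij")
    v = img.astype(int)
    out = (
        (1 - TV) * (1 - TU) * luts[RL, CL, v]
        + (1 - TV) * TU * luts[RL, CH, v]
        + TV * (1 - TU) * luts[RH, CL, v]
        + TV * TU * luts[RH, CH, v]
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# BT.601 full-range luma/chroma coefficients
_YCBCR = np.array(
    [[0.299, 0.587, 0.114], [-0.168736, -0.331264, 0.5], [0.5, -0.418688, -0.081312]]
)
_YCBCR_INV = np.linalg.inv(_YCBCR)


def clahe(img: GrayImage | RgbImage, params: ClaheParams | None = None):
    """Contrast-limited adaptive histogram equalization.

    Gray images are equalized directly; colour images on the luminance
    channel only.  Returns the same container type as the input.
    """
    params = params or ClaheParams()
    if isinstance(img, RgbImage):
        rgb = img.pixels.astype(np.float64)
        ycc = rgb @ _YCBCR.T
        y = np.clip(np.round(ycc[:, :, 0]), 0, 255).astype(np.uint8)
        ycc[:, :, 0] = _clahe_gray(y, params)
        out = np.clip(np.round(ycc @ _YCBCR_INV.T), 0, 255).astype(np.uint8)
        return RgbImage(out)
    if isinstance(img, GrayImage):
        return GrayImage(_clahe_gray(img.pixels, params))
    return _clahe_gray(np.asarray(img, dtype=np.uint8), params)


def median_filter(img: GrayImage | RgbImage, params: MedianParams | None = None):
    """Median filter with symmetric padding (edge pixels duplicated into the
    virtual border: sequence a,b,c pads as a,a,b,c).  Channels of colour
    images are filtered independently."""
    params = params or MedianParams()
    px = img.pixels if isinstance(img, (GrayImage, RgbImage)) else np.asarray(img)
    if px.ndim == 3:
        out = np.stack(
            [
                ndimage.median_filter(px[:, :, c], size=params.window, mode="reflect")
                for c in range(px.shape[2])
            ],
            axis=2,
        )
    else:
        out = ndimage.median_filter(px, size=params.window, mode="reflect")
    if isinstance(img, RgbImage):
        return RgbImage(out)
    if isinstance(img, GrayImage):
        return GrayImage(out)
    return out
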