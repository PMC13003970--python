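"""Baseline rice segmentation: excess-green transform plus Otsu thresholding.

The ExG vegetation index, 2G − R − B, amplifies the green canopy against
soil and water.  Otsu's method then picks the histogram threshold that
maximizes between-class variance.  ExG values (range [−510, 510]) are
mapped to the byte range by the fixed affine (v + 510)·255/1020 before
thresholding so that thresholds are comparable across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask, GrayImage, RgbImage

__all__ = ["ExgImage", "exg", "otsu_threshold", "segment_exg_otsu", "rescale_exg"]

# pure-background scenes produce a narrow unimodal ExG histogram; below this
# 1st–99th percentile spread (in byte levels; vegetated scenes span ≳50) the
# Otsu split is meaningless and the sign rule ExG > 0 is used instead
LOW_CONTRAST_SPAN = 32


@dataclass
class ExgImage:
    """Signed excess-green image, exact integer 2G − R − B per pixel."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int16)


def exg(img: RgbImage) -> ExgImage:
    """Excess-green index 2G − R − B, exact arithmetic, no clipping."""
    px = img.pixels.astype(np.int16) if isinstance(img, RgbImage) else np.asarray(img, dtype=np.int16)
    return ExgImage(2 * px[:, :, 1] - px[:, :, 0] - px[:, :, 2])


def rescale_exg(e: ExgImage | np.ndarray) -> np.ndarray:
    """Map signed ExG values onto [0, 255] by the fixed affine (v+510)·255/1020."""
    v = e.pixels if isinstance(e, ExgImage) else np.asarray(e)
    return np.round((v.astype(np.float64) + 510.0) * 255.0 / 1020.0).astype(np.uint8)


def otsu_threshold(gray: GrayImage | ExgImage | np.ndarray) -> tuple[int, bool]:
    """Otsu's threshold over the 256-bin histogram.

    Returns ``(t, degenerate)`` where the binarization rule is value > t.
    Ties in the between-class variance break toward the smallest t.  A
    constant image returns its single value with the degenerate flag set.
    """
    if isinstance(gray, ExgImage):
        vals = rescale_exg(gray)
    elif isinstance(gray, GrayImage):
        vals = gray.pixels
    else:
        vals = np.asarray(gray, dtype=np.uint8)
    hist = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        return int(vals.ravel()[0]), True

    # between-class variance for every candidate threshold t (class0 ≤ t)
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist) / n
    mu = np.cumsum(hist * levels) / n
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b)), False


def segment_exg_otsu(img: RgbImage) -> BinaryMask:
    """Segment rice pixels by thresholding the rescaled ExG image with Otsu.

    Degenerate or low-contrast scenes (constant, or 1st–99th percentile ExG
    spread under :data:`LOW_CONTRAST_SPAN` byte levels) fall back to the
    sign rule ExG > 0, which keeps the operation total and leaves
    plant-free scenes essentially empty.
    """
    e = exg(img)
    scaled = rescale_exg(e)
    t, degenerate = otsu_threshold(ExgImage(e.pixels))
    lo, hi = np.percentile(scaled, [1, 99])
    if degenerate or hi - lo < LOW_CONTRAST_SPAN:
        return BinaryMask((e.pixels > 0).astype(np.uint8))
    return BinaryMask((scaled > t).astype(np.uint8))
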