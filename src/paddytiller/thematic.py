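"""Thematic tiller-class mapping over a checkerboard grid.

Per-plot tiller estimates are aggregated on an equal-rectangle grid (the
cell size is the single scale parameter), classified into k classes (5 by
default) with Jenks natural breaks — the contiguous 1-D partition
minimizing within-class squared deviation, found by Fisher's dynamic
program — and rendered as a choropleth with a green ramp from light
(102, 255, 102) for the lowest class to dark (0, 153, 0) for the highest.

Geography is pixel-based: cells are rectangles in image coordinates and
the GeoJSON output uses (x=col, y=row) rings, with an optional affine
transform for georeferencing downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "GridCell",
    "ThematicGrid",
    "JenksResult",
    "grid_partition",
    "jenks_breaks",
    "classify_and_render",
    "class_colors",
    "legend_intervals",
    "EXAMPLE_FIELD_BREAKS",
    "example_field_legend",
]

RAMP_START = (102, 255, 102)
RAMP_END = (0, 153, 0)

# published example classing of a 576-plot field (plants per plot cell);
# shipped as a worked legend, not as defaults for new data
EXAMPLE_FIELD_BREAKS = (83.0, 114.0, 143.0, 171.0)


@dataclass
class GridCell:
    row: int
    col: int
    pixel_bounds: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    estimated_tillers: float = float("nan")
    class_index: int = 0  # 1-based once classified


@dataclass
class JenksResult:
    breaks: list[float]  # k−1 ascending class boundaries (upper bounds)
    gvf: float  # goodness of variance fit in [0, 1]


@dataclass
class ThematicGrid:
    cells: list[GridCell]
    scale_param: int
    breaks: list[float]
    colors: list[tuple[int, int, int]]
    gvf: float = float("nan")


def grid_partition(image_extent: tuple[int, int], scale_param: int) -> list[GridCell]:
    """Divide an (height, width) extent into scale×scale cells, row-major;
    the last row/column may be truncated.  Cells tile the extent exactly."""
    if scale_param < 1:
        raise ValueError("scale_param must be ≥ 1 px")
    h, w = image_extent
    cells = []
    nrows = int(np.ceil(h / scale_param))
    ncols = int(np.ceil(w / scale_param))
    for r in range(nrows):
        for c in range(ncols):
            cells.append(
                GridCell(
                    row=r,
                    col=c,
                    pixel_bounds=(
                        r * scale_param,
                        c * scale_param,
                        min((r + 1) * scale_param, h),
                        min((c + 1) * scale_param, w),
                    ),
                )
            )
    return cells


def _jenks_matrices(values: np.ndarray, k: int) -> np.ndarray:
    """Fisher's dynamic program over sorted values: lower class limits."""
    n = len(values)
    # prefix sums for O(1) within-class sum of squared deviations
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csq = np.concatenate([[0.0], np.cumsum(values**2)])

    def ssd(i: int, j: int) -> float:
        # values[i..j] inclusive, 0-based
        s = csum[j + 1] - csum[i]
        sq = csq[j + 1] - csq[i]
        m = j - i + 1
        return sq - s * s / m

    # cost[c][j]: minimal SSD of splitting values[0..j] into c classes
    cost = np.full((k + 1, n), np.inf)
    split = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        cost[1][j] = ssd(0, j)
    for c in range(2, k + 1):
        for j in range(c - 1, n):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j + 1):
                v = cost[c - 1][i - 1] + ssd(i, j)
                if v < best:
                    best, arg = v, i
            cost[c][j] = best
            split[c][j] = arg
    # recover class start indices
    starts = []
    j = n - 1
    for c in range(k, 1, -1):
        i = split[c][j]
        starts.append(i)
        j = i - 1
    starts.reverse()
    return np.array(starts), float(cost[k][n - 1])


def jenks_breaks(values, k: int) -> JenksResult:
    """Jenks natural breaks: k contiguous classes of the sorted values with
    minimal total within-class squared deviation.

    Breaks are the upper values of classes 1..k−1.  Deterministic; if the
    data carry fewer distinct values than k the classes collapse (a
    warning is raised).
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    if not (n >= k >= 2):
        raise ValueError("need n ≥ k ≥ 2")
    if len(np.unique(vals)) < k:
        warnings.warn("fewer distinct values than classes; classes collapse", stacklevel=2)
    starts, best_cost = _jenks_matrices(vals, k)
    breaks = [float(vals[i - 1]) for i in starts]
    sdam = float(((vals - vals.mean()) ** 2).sum())
    gvf = 1.0 if sdam == 0 else 1.0 - best_cost / sdam
    return JenksResult(breaks=breaks, gvf=gvf)


def class_colors(k: int) -> list[tuple[int, int, int]]:
    """Linear green ramp over k classes from RAMP_START to RAMP_END."""
    if k < 2:
        raise ValueError("need at least 2 classes")
    out = []
    for i in range(k):
        t = i / (k - 1)
        out.append(
            tuple(int(round(a + t * (b - a))) for a, b in zip(RAMP_START, RAMP_END))
        )
    return out


def legend_intervals(breaks, integer: bool = True) -> list[str]:
    """Legend strings in the ≤b₁, b₁+1–b₂, …, ≥b₄ style for integer counts."""
    b = [float(x) for x in breaks]
    if integer:
        b = [int(round(x)) for x in b]
        entries = [f"≤{b[0]}"]
        for lo, hi in zip(b[:-1], b[1:]):
            entries.append(f"{lo + 1}–{hi}")
        entries.append(f"≥{b[-1] + 1}")
        return entries
    entries = [f"≤{b[0]:g}"]
    for lo, hi in zip(b[:-1], b[1:]):
        entries.append(f"{lo:g}–{hi:g}")
    entries.append(f">{b[-1]:g}")
    return entries


def example_field_legend() -> list[str]:
    """The packaged example legend for the published 576-plot field
    classing (plants per plot cell)."""
    return legend_intervals(EXAMPLE_FIELD_BREAKS)


def _classify(value: float, breaks: list[float]) -> int:
    """1-based class index: class i covers values ≤ breaks[i-1]."""
    for i, b in enumerate(breaks):
        if value <= b:
            return i + 1
    return len(breaks) + 1


def classify_and_render(
    cells: list[GridCell],
    estimates,
    k: int = 5,
    image_extent: tuple[int, int] | None = None,
    out_png: str | None = None,
    out_geojson: str | None = None,
) -> ThematicGrid:
    """Classify per-cell estimates with Jenks breaks and render the map.

    Returns the ThematicGrid; optionally writes a PNG choropleth and a
    GeoJSON FeatureCollection (one polygon per cell with
    estimated_tillers, class_index and color properties).
    """
    est = np.asarray(estimates, dtype=float)
    if len(est) != len(cells):
        raise ValueError("one estimate per cell required")
    if k < 2:
        raise ValueError("need at least 2 classes")
    res = jenks_breaks(est, k)
    colors = class_colors(k)
    grid_cells = []
    for cell, e in zip(cells, est):
        grid_cells.append(
            GridCell(
                row=cell.row,
                col=cell.col,
                pixel_bounds=cell.pixel_bounds,
                estimated_tillers=float(e),
                class_index=_classify(float(e), res.breaks),
            )
        )
    scale = max(b[3] - b[1] for b in (c.pixel_bounds for c in cells))
    grid = ThematicGrid(
        cells=grid_cells,
        scale_param=scale,
        breaks=res.breaks,
        colors=colors,
        gvf=res.gvf,
    )
    if out_png is not None:
        h = max(c.pixel_bounds[2] for c in grid_cells)
        w = max(c.pixel_bounds[3] for c in grid_cells)
        if image_extent is not None:
            h, w = image_extent
        img = np.zeros((h, w, 3), dtype=np.uint8)
        for c in grid_cells:
            r0, c0, r1, c1 = c.pixel_bounds
            img[r0:r1, c0:c1] = colors[c.class_index - 1]
        Image.fromarray(img).save(out_png)
    if out_geojson is not None:
        features = []
        for c in grid_cells:
            r0, c0, r1, c1 = c.pixel_bounds
            ring = [[c0, r0], [c1, r0], [c1, r1], [c0, r1], [c0, r0]]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "row": c.row,
                        "col": c.col,
                        "estimated_tillers": c.estimated_tillers,
                        "class_index": c.class_index,
                        "color": list(colors[c.class_index - 1]),
                    },
                }
            )
        doc = {
            "type": "FeatureCollection",
            "features": features,
            "properties": {
                "breaks": grid.breaks,
                "gvf": grid.gvf,
                "legend": legend_intervals(grid.breaks),
            },
        }
        with open(out_geojson, "w") as fh:
            json.dump(doc, fh)
    return grid
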