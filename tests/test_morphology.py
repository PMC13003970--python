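import itertools

import numpy as np
import pytest
from skimage.draw import disk

from paddytiller.morphology import (
    PlantRegion,
    convex_hull,
    distance_transform,
    label_components,
    min_area_rect,
    split_adhered,
)


def brute_hull_area(points: np.ndarray) -> float:
    """O(n³)-flavoured oracle: hull = points not strictly inside any
    triangle of other points; area via shoelace on the angularly sorted
    hull."""
    pts = np.unique(points.astype(float), axis=0)
    if len(pts) < 3:
        return 0.0

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def in_triangle(p, a, b, c):
        d1 = cross2(b - a, p - a)
        d2 = cross2(c - b, p - b)
        d3 = cross2(a - c, p - c)
        return (min(d1, d2, d3) > 1e-12) or (max(d1, d2, d3) < -1e-12)

    hull = []
    for p in pts:
        inside = False
        for a, b, c in itertools.combinations([q for q in pts if not np.array_equal(q, p)], 3):
            if in_triangle(p, a, b, c):
                inside = True
                break
        if not inside:
            hull.append(p)
    hull = np.array(hull)
    ctr = hull.mean(axis=0)
    ang = np.arctan2(hull[:, 1] - ctr[1], hull[:, 0] - ctr[0])
    hull = hull[np.argsort(ang)]
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rect_area_sweep(points: np.ndarray) -> float:
    """Minimum enclosing-rectangle area over angles 0–90° in 0.1° steps."""
    best = np.inf
    pts = points.astype(float)
    for deg in np.arange(0, 90, 0.1):
        t = np.radians(deg)
        rot = pts @ np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        ext = rot.max(axis=0) - rot.min(axis=0)
        best = min(best, ext[0] * ext[1])
    return best


class TestLabelComponents:
    def test_two_disjoint_squares(self):
        m = np.zeros((20, 20), np.uint8)
        m[2:7, 2:7] = 1
        m[10:15, 10:15] = 1
        regs = label_components(m, min_area=1)
        assert [r.area_px for r in regs] == [25, 25]
        assert [r.id for r in regs] == [0, 1]

    def test_diagonal_touch_is_one_region(self):
        m = np.zeros((4, 4), np.uint8)
        m[1, 1] = m[2, 2] = 1
        assert len(label_components(m, min_area=1)) == 1

    def test_min_area_filters_specks(self):
        m = np.zeros((30, 30), np.uint8)
        m[2:12, 2:12] = 1  # 100 px
        m[20:22, 20:25] = 1  # 10 px speck
        assert len(label_components(m, min_area=50)) == 1

    def test_region_invariants(self):
        m = np.zeros((10, 10), np.uint8)
        m[2:8, 3:7] = 1
        reg = label_components(m, min_area=1)[0]
        assert reg.area_px == len(reg.pixel_coords)
        contour_set = {tuple(p) for p in reg.contour}
        pixel_set = {tuple(p) for p in reg.pixel_coords}
        assert contour_set <= pixel_set


class TestDistanceTransform:
    def test_single_pixel_distance_one(self):
        m = np.zeros((5, 5), np.uint8)
        m[2, 2] = 1
        assert distance_transform(m)[2, 2] == 1.0

    def test_disc_core_depth_matches_radius(self):
        m = np.zeros((16, 16), bool)
        rr, cc = disk((8, 8), 5)
        m[rr, cc] = True
        d = distance_transform(m.astype(np.uint8))
        assert abs(d.max() - 5) <= 0.5

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(10):
            m = rng.random((16, 16)) < 0.6
            d = distance_transform(m.astype(np.uint8))
            bg = np.argwhere(~m)
            for r in range(16):
                for c in range(16):
                    if not m[r, c]:
                        assert d[r, c] == 0
                    elif len(bg):
                        expected = np.sqrt(((bg - [r, c]) ** 2).sum(axis=1)).min()
                        assert d[r, c] == pytest.approx(expected)

    def test_all_foreground_measures_to_border(self):
        m = np.ones((5, 5), np.uint8)
        d = distance_transform(m)
        assert d[0, 0] == 1.0 and d[2, 2] == 3.0


class TestSplitAdhered:
    def test_single_disc_unchanged(self):
        m = np.zeros((30, 30), bool)
        rr, cc = disk((15, 15), 8)
        m[rr, cc] = True
        reg = label_components(m.astype(np.uint8), 1)[0]
        parts = split_adhered(reg)
        assert len(parts) == 1
        assert {tuple(p) for p in parts[0].pixel_coords} == {
            tuple(p) for p in reg.pixel_coords
        }

    def test_two_overlapping_discs_partition_and_centroids(self):
        m = np.zeros((40, 50), bool)
        for ctr in ((20, 18), (20, 30)):
            rr, cc = disk(ctr, 8)
            m[rr, cc] = True
        reg = label_components(m.astype(np.uint8), 1)[0]
        parts = split_adhered(reg)
        assert len(parts) == 2
        assert sum(p.area_px for p in parts) == reg.area_px
        union = set()
        for p in parts:
            part_set = {tuple(q) for q in p.pixel_coords}
            assert not (union & part_set)
            union |= part_set
        assert union == {tuple(q) for q in reg.pixel_coords}
        got = sorted((p.centroid for p in parts), key=lambda c: c[1])
        for (gr, gc), (tr, tc) in zip(got, ((20, 18), (20, 30))):
            assert np.hypot(gr - tr, gc - tc) <= 2.0

    def test_dumbbell_splits_at_bridge(self):
        m = np.zeros((15, 30), np.uint8)
        m[3:12, 2:11] = 1
        m[3:12, 19:28] = 1
        m[7, 11:19] = 1
        parts = split_adhered(label_components(m, 1)[0])
        assert len(parts) == 2
        assert sorted(p.area_px for p in parts) == [85, 85]


class TestConvexHull:
    def test_filled_square_hull_area(self):
        m = np.zeros((15, 15), np.uint8)
        m[2:12, 2:12] = 1
        _, area = convex_hull(label_components(m, 1)[0])
        assert area == 81.0  # pixel centers span 9×9

    def test_right_triangle(self):
        _, area = convex_hull(np.array([[0, 0], [0, 4], [3, 0]]))
        assert area == 6.0

    def test_collinear_degenerate(self):
        _, area = convex_hull(np.array([[0, 0], [0, 3], [0, 7]]))
        assert area == 0.0

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(8):
            pts = rng.integers(0, 15, (20, 2))
            _, area = convex_hull(pts)
            ref = brute_hull_area(pts[:, ::-1])
            assert area == pytest.approx(ref, abs=1e-9)


class TestMinAreaRect:
    def test_axis_aligned_block(self):
        m = np.zeros((30, 40), np.uint8)
        m[5:15, 5:25] = 1
        r = min_area_rect(label_components(m, 1)[0])
        assert (r.width_px, r.height_px) == (19.0, 9.0)
        assert r.angle == pytest.approx(0.0, abs=1e-9)

    def test_rotated_block_recovers_angle_and_area(self):
        base = np.array([(r, c) for r in range(10) for c in range(20)], float)
        t = np.radians(45)
        rot = base @ np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        coords = np.unique(np.round(rot).astype(int) + 30, axis=0)
        r = min_area_rect(coords)
        assert r.width_px * r.height_px <= 1.10 * 19 * 9
        assert abs(r.angle - 45) <= 3.0

    def test_matches_angle_sweep_on_random_clouds(self, rng):
        for _ in range(5):
            coords = rng.integers(0, 25, (15, 2))
            r = min_area_rect(coords)
            ref = rect_area_sweep(np.unique(coords, axis=0).astype(float))
            if ref > 0:
                assert r.width_px * r.height_px <= 1.10 * ref + 1e-9

    def test_collinear_row_degenerates(self):
        coords = np.array([[3, c] for c in range(2, 9)])
        r = min_area_rect(coords)
        assert r.width_px == 6.0 and r.height_px == 0.0

    def test_rect_area_never_exceeds_axis_aligned_bbox(self, rng):
        for _ in range(5):
            coords = rng.integers(0, 30, (25, 2))
            coords = np.unique(coords, axis=0)
            r = min_area_rect(coords)
            ext = coords.max(axis=0) - coords.min(axis=0)
            assert r.width_px * r.height_px <= ext[0] * ext[1] + 1e-6


def test_region_requires_pixels():
    with pytest.raises(ValueError):
        PlantRegion(id=0, pixel_coords=np.empty((0, 2)), shape=(4, 4))
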