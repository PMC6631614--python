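"""Shape descriptors vs closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

import cocoonsort as cs
from cocoonsort.errors import DegenerateRegionError
from cocoonsort.features import RegionShape, _boundary_corner_points


def square_region(side, offset=(2, 2)):
    mask = np.zeros((side + 2 * offset[0] + 1, side + 2 * offset[1] + 1), dtype=bool)
    mask[offset[0] : offset[0] + side, offset[1] : offset[1] + side] = True
    return RegionShape.from_mask(mask)


def disc_region(radius):
    n = 2 * radius + 9
    yy, xx = np.mgrid[0:n, 0:n]
    return RegionShape.from_mask((yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= radius**2)


def rotated_rect_region(a, b, theta):
    n = int(np.hypot(a, b)) + 8
    yy, xx = np.mgrid[0:n, 0:n] - n / 2.0
    xr = np.cos(theta) * xx + np.sin(theta) * yy
    yr = -np.sin(theta) * xx + np.cos(theta) * yy
    return RegionShape.from_mask((np.abs(xr) <= a / 2) & (np.abs(yr) <= b / 2))


def brute_force_perimeter(region):
    """Exhaustive scan: pixels of the region with an exterior 4-neighbour."""
    filled = {tuple(p) for p in region.filled}
    count = 0
    for r, c in filled:
        if any((r + dr, c + dc) not in filled for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))):
            count += 1
    return count


def gift_wrap_hull(points):
    """Jarvis-march convex hull over a point cloud (independent oracle)."""
    pts = sorted({(float(p[0]), float(p[1])) for p in points})
    start = min(pts)
    hull, current = [start], start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            dist_p = (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
            dist_c = (candidate[0] - current[0]) ** 2 + (candidate[1] - current[1]) ** 2
            if cross < 0 or (cross == 0 and dist_p > dist_c):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    return hull


class TestAreaPerimeter:
    def test_square_area_and_perimeter(self):
        region = square_region(10)
        assert cs.area(region) == 100
        assert cs.perimeter(region) == 36  # 4*10 - 4 corner double counts

    def test_single_pixel(self):
        region = RegionShape.from_mask(np.array([[True]]))
        assert cs.area(region) == 1

    def test_line_perimeter_counts_every_pixel(self):
        mask = np.zeros((3, 12), dtype=bool)
        mask[1, 1:11] = True
        assert cs.perimeter(RegionShape.from_mask(mask)) == 10

    @pytest.mark.parametrize("seed", range(3))
    def test_perimeter_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((24, 24)) < 0.5
        comps = cs.extract_components(mask, min_size=2)
        assert comps, "fixture produced no components"
        for region in comps[:3]:
            assert cs.perimeter(region) == brute_force_perimeter(region)

    def test_rendered_superellipse_area_matches_closed_form(self):
        img = cs.render_silhouette(center=(64, 64), scale=22.0, image_size=(160, 160))
        region = cs.extract_components(cs.binarize(img, cs.otsu_threshold(img)))[0]
        expected = cs.superellipse_area(22.0 * 1.6, 22.0, 2.5)
        assert cs.area(region) == pytest.approx(expected, rel=0.02)


class TestMomentEllipse:
    def test_rectangle_axis_ratio_approaches_side_ratio(self):
        lam1, lam2 = cs.moment_ellipse(rotated_rect_region(80, 40, 0.0))
        assert lam1 / lam2 == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("radius", [20, 35])
    def test_disc_axes_equal_diameter(self, radius):
        lam1, lam2 = cs.moment_ellipse(disc_region(radius))
        assert lam1 == pytest.approx(2 * radius, rel=0.02)
        assert lam2 == pytest.approx(2 * radius, rel=0.02)

    def test_rotation_by_90_degrees_preserves_axes(self, clean_silhouette_region):
        region = clean_silhouette_region
        mask = region.to_mask()
        rotated = RegionShape.from_mask(np.rot90(mask))
        assert cs.moment_ellipse(rotated) == pytest.approx(cs.moment_ellipse(region))

    def test_single_pixel_has_nonzero_extent(self):
        # the +1/12 correction gives an isolated pixel a finite moment ellipse
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(DegenerateRegionError):
            cs.moment_ellipse(RegionShape.from_mask(mask))  # < 2 pixels is still degenerate
        lam1, lam2 = cs.moment_ellipse(square_region(2))
        assert lam2 > 0


class TestMinBoundingRectangle:
    def test_axis_aligned_rectangle_recovered(self):
        lb, wb, ar = cs.min_bounding_rectangle(rotated_rect_region(30, 18, 0.0))
        assert lb == pytest.approx(30, abs=1)
        assert wb == pytest.approx(18, abs=1)
        assert ar == pytest.approx(lb * wb)

    def test_rotated_rectangle_dimensions_within_3_percent(self):
        lb, wb, _ = cs.min_bounding_rectangle(rotated_rect_region(60, 36, np.pi / 4))
        assert lb == pytest.approx(60, rel=0.03)
        assert wb == pytest.approx(36, rel=0.03)

    def test_never_larger_than_axis_aligned_box(self, clean_silhouette_region):
        region = clean_silhouette_region
        _, _, ar = cs.min_bounding_rectangle(region)
        extent = region.filled.max(axis=0) - region.filled.min(axis=0) + 1
        assert ar <= extent[0] * extent[1] + 1e-9

    def test_one_pixel_wide_line_has_unit_width_rectangle(self):
        # under the pixel-square convention even a collinear pixel run spans
        # a 1-px-wide rectangle rather than degenerating to a segment
        mask = np.zeros((3, 8), dtype=bool)
        mask[1, 1:7] = True
        lb, wb, ar = cs.min_bounding_rectangle(RegionShape.from_mask(mask))
        assert (lb, wb, ar) == pytest.approx((6.0, 1.0, 6.0))


class TestConvexHull:
    def test_convex_region_hull_area_close_to_region_area(self):
        region = square_region(12)
        h, _ = cs.convex_hull_geometry(region)
        assert h == pytest.approx(144, rel=0.01)

    def test_hull_polygon_matches_gift_wrapping_oracle(self, clean_silhouette_region):
        from cocoonsort.features import convex_hull_polygon

        region = clean_silhouette_region
        hull = convex_hull_polygon(region)
        oracle = Polygon(gift_wrap_hull(region.boundary))
        assert hull.equals(oracle)
        assert hull.length == pytest.approx(oracle.length, abs=1e-9)

    def test_hull_area_counts_convex_image_pixels(self):
        # brute-force convex-image count: pixel centers inside the hull
        region = disc_region(15)
        h, _ = cs.convex_hull_geometry(region)
        oracle_poly = Polygon(gift_wrap_hull(region.boundary))
        count = sum(
            1
            for r in range(int(region.filled[:, 0].min()), int(region.filled[:, 0].max()) + 1)
            for c in range(int(region.filled[:, 1].min()), int(region.filled[:, 1].max()) + 1)
            if oracle_poly.buffer(1e-9).contains(shapely.geometry.Point(r, c))
        )
        assert h == count

    def test_dumbbell_hull_strictly_exceeds_area(self):
        mask = np.zeros((12, 30), dtype=bool)
        mask[2:10, 2:10] = True
        mask[2:10, 20:28] = True
        mask[5:7, 10:20] = True  # thin bar
        region = cs.extract_components(mask, min_size=1)[0]
        h, _ = cs.convex_hull_geometry(region)
        assert h > cs.area(region)


class TestComputeShapeFeatures:
    def test_digital_disc_circularity_limits(self):
        # pixel-count perimeter of a digital disc ~ 4*sqrt(2)*r, so A/P^2 -> pi/32;
        # the Euclidean-perimeter variant recovers the continuum 1/(4*pi)
        region = disc_region(40)
        a = cs.area(region)
        assert a / cs.perimeter(region) ** 2 == pytest.approx(math.pi / 32, rel=0.10)
        assert a / cs.perimeter(region, method="euclidean") ** 2 == pytest.approx(
            1 / (4 * math.pi), rel=0.10
        )

    @pytest.mark.parametrize("make", [lambda: disc_region(25), lambda: square_region(20),
                                      lambda: rotated_rect_region(40, 26, 0.5)])
    def test_solidity_of_convex_shapes_near_one(self, make):
        sf = cs.compute_shape_features(make())
        assert 0.98 <= sf.S <= 1.0

    def test_rectangle_rectangularity_approaches_one(self):
        sf = cs.compute_shape_features(rotated_rect_region(60, 40, 0.0))
        assert sf.R == pytest.approx(1.0, abs=0.02)

    def test_invariant_ordering_area_hull_rectangle(self, pm_batch):
        records, _ = pm_batch
        for r in records:
            v = cs.segment_image(r.image, (400, 700))
            sf = cs.compute_shape_features(v.cocoon)
            h, _ = cs.convex_hull_geometry(v.cocoon)
            _, _, ar = cs.min_bounding_rectangle(v.cocoon)
            assert sf.A <= h <= ar + 1e-9
            assert 0 < sf.R <= 1 and 0 < sf.S <= 1
            assert sf.E >= 1 and sf.axis_ratio >= 1 and sf.C > 0

    def test_translation_invariance(self):
        sf1 = cs.compute_shape_features(square_region(11, offset=(2, 2)))
        sf2 = cs.compute_shape_features(square_region(11, offset=(7, 4)))
        assert sf1.as_array() == pytest.approx(sf2.as_array())

    def test_dimensionless_features_stable_under_2x_scale(self):
        def features_at(scale):
            img = cs.render_silhouette(
                center=(96, 96), scale=scale, waist=0.08, angle=0.4, image_size=(192, 192)
            )
            region = cs.extract_components(cs.binarize(img, cs.otsu_threshold(img)))[0]
            return cs.compute_shape_features(region)

        sf1, sf2 = features_at(14.0), features_at(28.0)
        for name in ("axis_ratio", "E", "R", "S", "AC"):
            assert getattr(sf2, name) == pytest.approx(getattr(sf1, name), rel=0.05)

    def test_gender_size_signal_present_in_features(self, pm_batch):
        records, _ = pm_batch
        by_gender = {0: [], 1: []}
        for r in records:
            sf = cs.compute_shape_features(cs.segment_image(r.image, (400, 700)).cocoon)
            by_gender[r.true_label].append((sf.A, sf.P))
        male, female = np.mean(by_gender[1], axis=0), np.mean(by_gender[0], axis=0)
        assert female[0] > male[0]  # female area larger
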