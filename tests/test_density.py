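"""Density mapping: whole-retina density, KDE closed forms, quadrants."""

import math

import numpy as np
import pytest

from rgcquant.density import (
    isodensity_map,
    quadrant_partition,
    quadrant_stats,
    whole_retina_density,
)
from rgcquant.imgio import CentroidSet
from rgcquant.segmentation import RetinaMask


def square_mask(side_px, px=1.0):
    return RetinaMask(np.ones((side_px, side_px), bool), px)


def cs(points):
    pts = np.asarray(points, float)
    return CentroidSet(x=pts[:, 0], y=pts[:, 1])


class TestWholeRetinaDensity:
    def test_zero_cells(self):
        assert whole_retina_density(cs(np.empty((0, 2))), 4.0) == 0.0

    def test_arithmetic(self):
        assert whole_retina_density(cs(np.zeros((100, 2))), 4.0) == 25.0

    def test_published_pair(self):
        # 44,499 cells over 13.998 mm^2 gives the published mouse density
        pts = np.zeros((44499, 2))
        assert whole_retina_density(cs(pts), 13.998) == pytest.approx(3179, rel=1e-3)

    def test_zero_area_is_domain_error(self):
        with pytest.raises(ValueError):
            whole_retina_density(cs(np.zeros((1, 2))), 0.0)


class TestIsodensityMapClosedForms:
    def test_single_cell_peak_value(self):
        """Peak of a one-cell map is 1e6 / (2 pi sigma^2) cells/mm^2."""
        m = square_mask(1001)
        dm = isodensity_map(cs([(500.0, 500.0)]), m, bandwidth=100.0, grid_spacing=25.0,
                            method="direct")
        expected = 1e6 / (2 * math.pi * 100.0**2)
        assert expected == pytest.approx(15.9155, abs=1e-3)
        assert dm.grid.max() == pytest.approx(expected, rel=1e-6)

    def test_gaussian_profile_at_one_bandwidth(self):
        m = square_mask(1001)
        dm = isodensity_map(cs([(500.0, 500.0)]), m, bandwidth=100.0, grid_spacing=25.0,
                            method="direct")
        x, y = dm.node_coordinates()
        j = int(np.argmin(np.abs(x - 600.0)))  # 100 um = one sigma away
        i = int(np.argmin(np.abs(y - 500.0)))
        peak = 1e6 / (2 * math.pi * 100.0**2)
        assert dm.grid[i, j] == pytest.approx(peak * math.exp(-0.5), rel=1e-6)
        assert peak * math.exp(-0.5) == pytest.approx(9.653, abs=1e-3)

    def test_linearity_in_cell_count(self):
        m = square_mask(401)
        rng = np.random.default_rng(0)
        pts = rng.uniform(100, 300, (40, 2))
        single = isodensity_map(cs(pts), m, method="direct")
        doubled = isodensity_map(cs(np.vstack([pts, pts])), m, method="direct")
        np.testing.assert_allclose(doubled.grid, 2 * single.grid, rtol=1e-9)

    def test_mass_conservation(self):
        """Map integrates to the cell count when cells are >= 3 sigma inside."""
        m = square_mask(1601)
        rng = np.random.default_rng(1)
        pts = rng.uniform(400, 1200, (200, 2))  # 400 um = 4 sigma margin
        for method in ("direct", "fft"):
            dm = isodensity_map(cs(pts), m, bandwidth=100.0, grid_spacing=25.0,
                                method=method)
            assert dm.total_mass() == pytest.approx(200, rel=0.01)

    def test_fft_agrees_with_direct(self):
        m = square_mask(801)
        rng = np.random.default_rng(2)
        pts = rng.uniform(150, 650, (60, 2))
        d = isodensity_map(cs(pts), m, method="direct")
        f = isodensity_map(cs(pts), m, method="fft")
        # binning displaces cells by < grid_spacing/sqrt(2); compare loosely
        assert np.abs(f.grid - d.grid).max() / d.grid.max() < 0.05
        assert f.total_mass() == pytest.approx(d.total_mass(), rel=0.01)

    def test_translation_equivariance_on_grid_multiples(self):
        m = square_mask(601)
        pts = np.array([(200.0, 200.0), (320.0, 240.0)])
        a = isodensity_map(cs(pts), m, method="direct")
        b = isodensity_map(cs(pts + 50.0), m, method="direct")
        # shift by two grid nodes (50 um at 25 um spacing)
        np.testing.assert_allclose(a.grid[:-2, :-2], b.grid[2:, 2:], rtol=1e-9)

    def test_empty_set_is_domain_error(self):
        with pytest.raises(ValueError):
            isodensity_map(cs(np.empty((0, 2))), square_mask(101))


class TestQuadrantPartition:
    def test_up_right_point_is_dorsonasal_for_right_eye(self):
        part = quadrant_partition((0.0, 0.0), 90.0, "right")
        # image y axis points down, so "up-right on screen" is (+x, -y)
        assert part.label_points([10.0], [-10.0])[0] == "DN"

    def test_rotating_dorsal_axis_permutes_labels(self):
        p0 = quadrant_partition((0.0, 0.0), 90.0)
        p90 = quadrant_partition((0.0, 0.0), 180.0)
        xs = np.array([30.0, -40.0, 5.0, -5.0])
        ys = np.array([-5.0, 5.0, 30.0, -40.0])
        l0 = p0.label_points(xs, ys)
        # rotate the points along with the axis (90 deg CCW on the display)
        l90 = p90.label_points(ys, -xs)
        np.testing.assert_array_equal(l0, l90)

    def test_boundary_is_half_open(self):
        part = quadrant_partition((0.0, 0.0), 90.0, "right")
        # a point exactly on the dorsal axis belongs to the CCW sector (DT)
        assert part.label_points([0.0], [-10.0])[0] == "DT"

    def test_every_point_gets_exactly_one_label(self):
        part = quadrant_partition((0.0, 0.0), 37.0, "left")
        rng = np.random.default_rng(0)
        labels = part.label_points(rng.normal(0, 50, 500), rng.normal(0, 50, 500))
        assert set(labels) <= {"DN", "DT", "VN", "VT"}

    def test_uniform_disc_splits_evenly(self):
        rng = np.random.default_rng(3)
        n = 40000
        r = 100 * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        part = quadrant_partition((0.0, 0.0), 90.0)
        labels = part.label_points(r * np.cos(th), r * np.sin(th))
        for q in ("DN", "DT", "VN", "VT"):
            assert np.mean(labels == q) == pytest.approx(0.25, abs=0.01)


class TestQuadrantStats:
    def test_counts_and_areas_sum_exactly(self, fish_retina):
        part = quadrant_partition(fish_retina.onh_center, fish_retina.dorsal_axis_angle)
        qs = quadrant_stats(fish_retina.truth_centroids, fish_retina.truth_mask, part)
        assert qs["count"].sum() == len(fish_retina.truth_centroids)
        assert qs["area_mm2"].sum() == pytest.approx(fish_retina.truth_mask.area, abs=1e-12)

    def test_all_cells_in_one_sector(self):
        m = square_mask(201)
        part = quadrant_partition((100.0, 100.0), 90.0, "right")
        pts = np.column_stack([np.full(10, 150.0), np.full(10, 60.0)])  # up-right
        qs = quadrant_stats(cs(pts), m, part)
        assert qs.loc["DN", "count"] == 10
        assert qs["count"].sum() == 10
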