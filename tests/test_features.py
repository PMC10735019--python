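"""Descriptor formulas against hand-computed values on enumerated shapes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackqc.features import (
    FEATURE_COLUMNS,
    PIXEL_AREA_UM2,
    area,
    aspect_ratio,
    clumpiness,
    describe,
    diameter,
    featurize_image,
    heterogeneity,
    parameter_histograms,
    px_area_to_um2,
    roundness,
    summarize,
)
from trackqc.objects import TrackObject

from conftest import disk_coords, make_object


class TestArea:
    def test_single_pixel(self):
        assert area(make_object([(0, 0)])) == 1

    def test_digital_disk_radius_3_has_29_lattice_points(self, disk3):
        assert area(disk3) == 29

    def test_ring_hole_not_counted(self):
        ring = [(r, c) for r in range(3) for c in range(3) if (r, c) != (1, 1)]
        obj = make_object(ring)
        assert area(obj) == 8
        assert area(obj, filled=True) == 9

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            TrackObject(np.empty((0, 2)), np.empty(0))


class TestDiameter:
    def test_single_pixel_is_zero(self):
        assert diameter(make_object([(5, 5)])) == 0.0

    def test_horizontal_row_of_five(self):
        obj = make_object([(0, c) for c in range(5)])
        assert diameter(obj) == pytest.approx(4.0)

    def test_disk_radius_3_diametral_chord(self, disk3):
        assert diameter(disk3) == pytest.approx(6.0)

    def test_translation_invariant(self, disk3):
        moved = make_object(disk3.coords + np.array([17, 31]))
        assert diameter(moved) == pytest.approx(diameter(disk3))


class TestAspectRatio:
    def test_disk_is_circular(self):
        obj = make_object(disk_coords(5))
        assert aspect_ratio(obj) == pytest.approx(1.0, abs=0.05)

    def test_rectangle_axis_ratio_equals_side_ratio(self, rect3x9):
        # uniform 3x9 block: per-axis variance (n^2-1)/12 plus the 1/12
        # pixel term gives exactly (9/3)^2 variance ratio
        assert aspect_ratio(rect3x9) == pytest.approx(3.0, abs=0.01)

    def test_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            coords = np.unique(rng.integers(0, 12, size=(15, 2)), axis=0)
            assert aspect_ratio(make_object(coords)) >= 1.0

    def test_single_pixel_wide_line_is_finite(self):
        obj = make_object([(0, c) for c in range(7)])
        assert np.isfinite(aspect_ratio(obj))
        assert aspect_ratio(obj) > 3


class TestRoundness:
    def test_analytic_circle_formula(self):
        # the formula itself: P = 2 pi r, A = pi r^2 gives exactly 1
        r = 13.7
        assert (2 * np.pi * r) ** 2 / (4 * np.pi * np.pi * r * r) == pytest.approx(1.0)

    def test_rectangle_under_declared_perimeter(self, rect3x9):
        # declared chain-code estimator: boundary length 20 for a 3x9
        # block, so roundness = 20^2 / (4 pi 27)
        assert roundness(rect3x9) == pytest.approx(400.0 / (4 * np.pi * 27), abs=1e-6)

    def test_digital_disk_radius_8_close_to_one(self):
        obj = make_object(disk_coords(8))
        assert 0.95 <= roundness(obj) <= 1.15


class TestHeterogeneity:
    def test_uniform_object_is_homogeneous(self, disk3):
        assert heterogeneity(disk3) == 0.0

    def test_single_deviant_pixel(self):
        # mean 103; only the 130 pixel deviates by more than 10.3
        obj = make_object([(0, c) for c in range(10)], [100.0] * 9 + [130.0])
        assert heterogeneity(obj) == pytest.approx(0.1)

    def test_alternating_extremes_fully_heterogeneous(self):
        obj = make_object([(0, c) for c in range(10)], [10.0, 200.0] * 5)
        assert heterogeneity(obj) == pytest.approx(1.0)

    def test_zero_mean_degenerate_case(self):
        obj = make_object([(0, 0), (0, 1)], [0.0, 0.0])
        assert heterogeneity(obj) == 0.0


class TestClumpiness:
    def test_gradient_rim_removed_by_erosion(self):
        # 7x7 square: uniform dark core, bright one-pixel rim
        coords = [(r, c) for r in range(7) for c in range(7)]
        vals = [
            60.0 if 1 <= r <= 5 and 1 <= c <= 5 else 160.0 for r, c in coords
        ]
        obj = make_object(coords, vals)
        assert heterogeneity(obj) > 0.4
        assert clumpiness(obj) == 0.0

    def test_object_smaller_than_structuring_element(self):
        obj = make_object([(0, 0), (0, 1), (1, 0)])
        assert clumpiness(obj) == 0.0

    def test_deviant_center_of_5x5(self):
        coords = [(r, c) for r in range(5) for c in range(5)]
        vals = [160.0 if (r, c) == (2, 2) else 100.0 for r, c in coords]
        obj = make_object(coords, vals)
        # eroded core is the central 3x3; only its center deviates >10%
        assert clumpiness(obj) == pytest.approx(1.0 / 9.0)

    def test_eroded_set_is_subset(self, disk3):
        # erosion monotonicity checked through the area bound
        assert clumpiness(disk3) == 0.0  # uniform anyway
        assert area(disk3) >= 1


class TestSummarize:
    def test_constant_list(self):
        stats = summarize([7.0] * 12)
        assert stats["iqr"] == 0.0 and stats["std"] == 0.0
        for key in ("mean", "median", "p5", "p90"):
            assert stats[key] == 7.0

    def test_1_to_100_under_linear_interpolation(self):
        stats = summarize(np.arange(1, 101, dtype=float))
        assert stats["median"] == pytest.approx(50.5)
        assert stats["p90"] == pytest.approx(90.1)
        assert stats["p5"] == pytest.approx(5.95)
        assert stats["iqr"] == pytest.approx(49.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_order_statistic_inequalities(self, values):
        stats = summarize(values)
        assert stats["p5"] <= stats["median"] <= stats["p90"]
        assert stats["iqr"] >= 0.0 and stats["std"] >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestInvariances:
    def rotate90(self, coords):
        return np.stack([coords[:, 1], -coords[:, 0]], axis=1)

    def test_translation_invariance_of_all_descriptors(self):
        rng = np.random.default_rng(5)
        coords = disk_coords(4) + rng.integers(10, 20, size=2)
        obj = make_object(coords, rng.uniform(30, 90, size=len(coords)))
        moved = make_object(coords + np.array([13, -7]), obj.intensities)
        assert describe(moved) == describe(obj)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        coords = np.unique(rng.integers(0, 9, size=(30, 2)), axis=0)
        vals = rng.uniform(30, 90, size=len(coords))
        obj = make_object(coords, vals)
        rot = make_object(self.rotate90(coords), vals)
        d0, d1 = describe(obj), describe(rot)
        assert d0.area == d1.area
        assert d0.heterogeneity == d1.heterogeneity
        assert d0.clumpiness == d1.clumpiness
        assert d0.diameter == pytest.approx(d1.diameter, rel=0.05, abs=0.5)
        assert d0.aspect == pytest.approx(d1.aspect, rel=0.05)


class TestFeaturize:
    def test_single_object_statistics_collapse(self, disk3):
        record = featurize_image([disk3])
        assert record["mean_area"] == record["p90_area"] == 29.0
        assert record["std_area"] == 0.0
        assert record["track_count"] == 1.0

    def test_vector_has_36_features(self, disk3, rect3x9):
        record = featurize_image([disk3, rect3x9])
        features = [k for k in record if k != "track_count"]
        assert sorted(features) == sorted(FEATURE_COLUMNS)
        assert len(features) == 36

    def test_pure_function(self, disk3, rect3x9):
        objs = [disk3, rect3x9]
        assert featurize_image(objs) == featurize_image(objs)

    def test_hand_computed_toy_table(self):
        """Three uniform squares: every area statistic by hand."""
        sizes = [2, 3, 5]
        objs = [
            make_object([(r, c) for r in range(s) for c in range(s)]) for s in sizes
        ]
        record = featurize_image(objs)
        areas = np.array([4.0, 9.0, 25.0])
        assert record["mean_area"] == pytest.approx(areas.mean())
        assert record["median_area"] == 9.0
        assert record["std_area"] == pytest.approx(areas.std())
        assert record["p90_area"] == pytest.approx(np.percentile(areas, 90))
        assert record["iqr_area"] == pytest.approx(
            np.percentile(areas, 75) - np.percentile(areas, 25)
        )

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            featurize_image([])


class TestHistogramsAndUnits:
    def test_histograms_normalized(self, disk3, rect3x9):
        for counts, _ in parameter_histograms([disk3, rect3x9]).values():
            assert counts.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_object_occupies_one_bin(self, disk3):
        for counts, _ in parameter_histograms([disk3]).values():
            assert np.count_nonzero(counts) == 1

    def test_pixel_to_um2(self):
        assert px_area_to_um2(0) == 0.0
        assert px_area_to_um2(1) == pytest.approx(0.02708, abs=2e-5)
        assert px_area_to_um2(30) == pytest.approx(0.812, abs=2e-3)
        assert PIXEL_AREA_UM2 == pytest.approx((211 / 1280) * (158 / 962))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            px_area_to_um2(-1)
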