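"""Geometry: ROI distances, membership and distance histograms."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box

from vesselbelt import (
    DistanceDistribution,
    PointPattern,
    RoiSet,
    distance_distribution,
    distance_to_roi,
)
from vesselbelt.errors import DegenerateInputError, GeometryError, LabelError
from vesselbelt.roi import histogram_distances


@pytest.fixture(scope="module")
def unit_square_roi():
    return RoiSet({"lumen": box(0.0, -1.0, 1.0, 0.0), "tumor": box(0.0, 0.0, 1.0, 5.0)})


class TestDistance:
    def test_inside_is_zero(self, unit_square_roi):
        assert distance_to_roi((0.5, -0.5), unit_square_roi, "lumen") == 0.0

    def test_axis_aligned_corner(self, unit_square_roi):
        # nearest boundary point of [0,1]x[-1,0] from (0, 1) is (0, 0)
        assert distance_to_roi((0.0, 1.0), unit_square_roi, "lumen") == pytest.approx(1.0)

    def test_missing_label_raises(self, unit_square_roi):
        with pytest.raises(LabelError):
            distance_to_roi((0, 0), unit_square_roi, "adjacent")

    def test_matches_shapely_on_irregular_polygon(self, rng):
        poly = Polygon([(0, 0), (4, 0), (4, 1), (2, 1), (2, 3), (0, 3)])
        roi = RoiSet({"tumor": poly})
        pts = rng.uniform(-2, 6, size=(500, 2))
        ours = roi.distances(pts, "tumor")
        ref = np.array([poly.distance(Point(*p)) for p in pts])
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_polygon_with_hole(self):
        outer = box(0, 0, 10, 10)
        holed = Polygon(outer.exterior.coords, [box(4, 4, 6, 6).exterior.coords])
        roi = RoiSet({"tumor": holed})
        # point at hole center is outside the region: 1 mm from the hole edge
        assert distance_to_roi((5.0, 5.0), roi, "tumor") == pytest.approx(1.0)
        assert distance_to_roi((1.0, 1.0), roi, "tumor") == 0.0

    def test_multipolygon_is_min_over_parts(self):
        parts = [box(0, 0, 1, 1), box(5, 0, 6, 1)]
        roi = RoiSet({"lumen": parts})
        merged = roi.distances(np.array([[3.0, 0.5]]), "lumen")[0]
        per_part = min(
            RoiSet({"lumen": p}).distances(np.array([[3.0, 0.5]]), "lumen")[0]
            for p in parts
        )
        assert merged == pytest.approx(per_part)
        assert merged == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        x=st.floats(-3, 3), y=st.floats(-3, 3),
        dx=st.floats(-0.5, 0.5), dy=st.floats(-0.5, 0.5),
    )
    def test_lipschitz(self, x, y, dx, dy):
        """Moving a query point by delta changes the distance by <= |delta|."""
        roi = RoiSet({"tumor": Polygon([(0, 0), (2, 0), (1, 1.5)])})
        d1 = distance_to_roi((x, y), roi, "tumor")
        d2 = distance_to_roi((x + dx, y + dy), roi, "tumor")
        assert abs(d1 - d2) <= np.hypot(dx, dy) + 1e-12

    def test_zero_area_polygon_rejected(self):
        degenerate = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(GeometryError):
            RoiSet({"tumor": degenerate})


class TestDistanceDistribution:
    def test_direct_binning(self):
        h = histogram_distances(np.array([0.05, 0.15, 0.15]), 0.1)
        np.testing.assert_array_equal(h.counts, [1, 2])
        assert h.edges[0] == 0.0
        assert h.bin_width == pytest.approx(0.1)

    def test_counts_sum_to_n(self, unit_square_roi, rng):
        pts = rng.uniform(0, 1, size=(137, 2)) * [1.0, 5.0]
        pat = PointPattern(pts, "tumor", 5.0)
        h = distance_distribution(pat, unit_square_roi, "lumen", 0.1)
        assert h.counts.sum() == 137

    def test_permutation_invariance(self, unit_square_roi, rng):
        pts = rng.uniform(0, 1, size=(50, 2)) * [1.0, 5.0]
        h1 = distance_distribution(PointPattern(pts), unit_square_roi, "lumen", 0.2)
        h2 = distance_distribution(
            PointPattern(pts[rng.permutation(50)]), unit_square_roi, "lumen", 0.2
        )
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_empty_pattern_flagged(self, unit_square_roi):
        with pytest.raises(DegenerateInputError):
            distance_distribution(PointPattern(np.empty((0, 2))), unit_square_roi, "lumen")

    def test_strip_area_expectation(self, unit_square_roi, rng):
        """CSR distances to an abutting edge are uniform: chi^2 GoF non-rejected."""
        from scipy import stats

        pts = np.column_stack([rng.uniform(0, 1, 4000), rng.uniform(0, 5, 4000)])
        h = distance_distribution(PointPattern(pts), unit_square_roi, "lumen", 0.5)
        expected = 4000 * np.diff(h.edges) / 5.0
        chi2 = ((h.counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(h.counts) - 1)
        assert p > 0.001

    def test_extension_pads_with_zeros(self):
        h = histogram_distances(np.array([0.05, 0.25]), 0.1)
        h2 = h.extended_to(5)
        assert h2.n_bins == 5
        assert h2.counts.sum() == h.counts.sum()
        np.testing.assert_array_equal(h2.counts[h.n_bins:], 0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceDistribution(np.array([0.1, 0.2]), np.array([1]))  # first edge != 0
        with pytest.raises(ValueError):
            DistanceDistribution(np.array([0.0, 0.1]), np.array([2]), n_points=3)


class TestRoiIO:
    def test_geojson_roundtrip(self, tmp_path, default_rois):
        path = tmp_path / "rois.geojson"
        default_rois.to_geojson(path)
        loaded = RoiSet.from_geojson(path)
        assert loaded.labels == default_rois.labels
        for label in loaded.labels:
            assert loaded.area(label) == pytest.approx(default_rois.area(label))

    def test_pixel_units_conversion(self, tmp_path):
        roi = RoiSet({"tumor": box(0, 0, 2000, 1000)})  # pixels
        path = tmp_path / "px.geojson"
        roi.to_geojson(path)
        loaded = RoiSet.from_geojson(path, units="pixel", mpp=0.5)
        assert loaded.area("tumor") == pytest.approx(1.0 * 0.5)  # 1 mm x 0.5 mm

    def test_label_aliases(self):
        roi = RoiSet({"IntestinalLumen": box(0, 0, 1, 1), "AdjacentTissue": box(2, 0, 3, 1)})
        assert "lumen" in roi and "adjacent" in roi
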