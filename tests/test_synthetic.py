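"""Generators: CSR patterns, planted belts and rendered IHC fixtures."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from vesselbelt import (
    BeltSpec,
    SyntheticLayout,
    generate_belt_pattern,
    generate_csr_points,
    render_ihc_image,
    segment_image,
)
from vesselbelt.errors import ConfigurationError, GeometryError
from vesselbelt.roi import PointPattern


class TestCsr:
    def test_zero_intensity_empty(self):
        pat = generate_csr_points(box(0, 0, 3, 3), 0.0, seed=0)
        assert pat.n_points == 0

    def test_poisson_count_moments(self):
        """Mean and variance of counts match Poisson(lambda * area) over 1000 reps."""
        region = box(0, 0, 1, 1)
        counts = np.array(
            [generate_csr_points(region, 100.0, seed=s).n_points for s in range(1000)]
        )
        assert abs(counts.mean() - 100.0) <= 1.0  # 3 * sqrt(100/1000)
        assert abs(counts.var(ddof=1) - 100.0) <= 15.0  # ~3 SE of the variance

    def test_points_inside_region(self):
        tri = Polygon([(0, 0), (4, 0), (0, 4)])
        pat = generate_csr_points(tri, 200.0, seed=1)
        assert pat.n_points > 0
        assert shapely.intersects_xy(tri, pat.points[:, 0], pat.points[:, 1]).all()

    def test_reproducible(self):
        a = generate_csr_points(box(0, 0, 2, 2), 50.0, seed=7)
        b = generate_csr_points(box(0, 0, 2, 2), 50.0, seed=7)
        np.testing.assert_array_equal(a.points, b.points)

    def test_degenerate_region(self):
        with pytest.raises(GeometryError):
            generate_csr_points(Polygon([(0, 0), (1, 0), (2, 0)]), 10.0, seed=0)


class TestBelt:
    def test_no_enrichment_zero_excess(self, default_layout):
        _, excess = generate_belt_pattern(default_layout, BeltSpec(50, 1.0, 1.0, "lumen", 0))
        assert excess == 0.0

    def test_closed_form_excess(self):
        # lambda = 50, k = 3, belt 0.2 mm x 10 mm = 2 mm^2 -> 50 * 2 * 2 = 200
        layout = SyntheticLayout()
        _, excess = generate_belt_pattern(layout, BeltSpec(50, 0.2, 3.0, "lumen", 0))
        assert excess == pytest.approx(200.0)

    def test_strip_counts_match_intensities(self):
        """Counts in/out of the belt match lambda*k and lambda within 3 SE (500 reps)."""
        layout = SyntheticLayout(domain_width=2.0, lumen_band_height=0.5,
                                 tumor_band_height=1.5, adjacent_band_height=0.5)
        lam, k, w = 50.0, 3.0, 0.5
        belt_area, rest_area = w * 2.0, (1.5 - w) * 2.0
        in_counts, out_counts = [], []
        for s in range(500):
            pat, _ = generate_belt_pattern(layout, BeltSpec(lam, w, k, "lumen", s))
            in_belt = pat.points[:, 1] < layout.tumor_top + w
            in_counts.append(in_belt.sum())
            out_counts.append((~in_belt).sum())
        mu_in, mu_out = lam * k * belt_area, lam * rest_area
        assert abs(np.mean(in_counts) - mu_in) <= 3 * np.sqrt(mu_in / 500)
        assert abs(np.mean(out_counts) - mu_out) <= 3 * np.sqrt(mu_out / 500)

    def test_k1_indistinguishable_from_csr(self, default_layout, default_rois):
        """With k = 1 the belt generator's distance distribution is CSR-like."""
        from scipy.stats import ks_2samp

        rejections = 0
        for s in range(20):
            belt, _ = generate_belt_pattern(
                default_layout, BeltSpec(30, 1.0, 1.0, "lumen", seed=s)
            )
            csr = generate_csr_points(default_layout.tumor_polygon(), 30.0, seed=1000 + s)
            d1 = default_rois.distances(belt.points, "lumen")
            d2 = default_rois.distances(csr.points, "lumen")
            if ks_2samp(d1, d2).pvalue < 0.05:
                rejections += 1
        assert rejections <= 5  # nominal rate would give 1 expected

    def test_belt_too_wide(self, default_layout):
        with pytest.raises(ConfigurationError):
            generate_belt_pattern(default_layout, BeltSpec(50, 6.0, 2.0, "lumen", 0))

    def test_adjacent_side_belt_position(self, default_layout):
        pat, _ = generate_belt_pattern(default_layout, BeltSpec(20, 1.0, 10.0, "adjacent", 3))
        # enrichment near the adjacent boundary: most points in the last mm
        frac_near = (pat.points[:, 1] > default_layout.tumor_bottom - 1.0).mean()
        assert frac_near > 0.5


class TestRender:
    def test_empty_pattern_background_only(self, render_layout):
        img, truth = render_ihc_image(
            PointPattern(np.empty((0, 2))), render_layout, seed=0
        )
        assert truth.empty
        assert len(segment_image(img, render_layout.mpp)) == 0

    def test_pixel_range_and_dtype(self, render_layout):
        pat = generate_csr_points(render_layout.tumor_polygon(), 100.0, seed=2)
        img, _ = render_ihc_image(pat, render_layout, seed=3, noise_sd=20.0)
        assert img.dtype == np.uint8
        assert img.min() >= 0 and img.max() <= 255

    def test_deterministic_and_truth_rows(self, render_layout):
        pat = generate_csr_points(render_layout.tumor_polygon(), 80.0, seed=4)
        img1, t1 = render_ihc_image(pat, render_layout, seed=5)
        img2, t2 = render_ihc_image(pat, render_layout, seed=5)
        np.testing.assert_array_equal(img1, img2)
        assert len(t1) == pat.n_points
        assert t1.equals(t2)

    def test_subpixel_vessels_rejected(self, render_layout):
        pat = generate_csr_points(render_layout.tumor_polygon(), 10.0, seed=6)
        with pytest.raises(ConfigurationError):
            render_ihc_image(pat, render_layout, major_axis_um=(0.2, 0.01), seed=0)


class TestLayout:
    def test_band_heights_sum(self, default_layout):
        assert default_layout.domain_height == pytest.approx(8.0)

    def test_roi_set_three_disjoint_labels(self, default_rois):
        assert default_rois.labels == ["adjacent", "lumen", "tumor"]
        inter = default_rois.geometry("tumor").intersection(default_rois.geometry("lumen"))
        assert inter.area == 0.0

    def test_invalid_extent(self):
        with pytest.raises(ConfigurationError):
            SyntheticLayout(tumor_band_height=-1.0)
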