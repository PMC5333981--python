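"""The excess statistic: E(x), x0, A, the Monte-Carlo null and significance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselbelt import (
    BeltSpec,
    PointPattern,
    excess_analysis,
    excess_profile,
    excess_significance,
    first_intersection_and_mass,
    generate_belt_pattern,
    generate_csr_points,
    simulate_controls,
)
from vesselbelt.errors import DegenerateInputError
from vesselbelt.roi import DistanceDistribution, histogram_distances


def _dd(counts, width=0.1):
    counts = np.asarray(counts)
    edges = np.arange(len(counts) + 1) * width
    return DistanceDistribution(edges, counts)


class TestExcessProfile:
    def test_hand_arithmetic(self):
        e = excess_profile(_dd([3, 1]), [_dd([2, 2]), _dd([1, 3])])
        np.testing.assert_allclose(e, [1.5, -1.5])

    def test_identical_controls_zero(self):
        obs = _dd([4, 3, 2])
        assert np.all(excess_profile(obs, [obs, obs]) == 0.0)

    def test_zero_sum(self, rng):
        obs = _dd(rng.multinomial(500, [0.25] * 4))
        ctrls = [_dd(rng.multinomial(500, [0.25] * 4)) for _ in range(30)]
        assert abs(excess_profile(obs, ctrls).sum()) < 1e-9 * 500

    def test_mismatched_widths_rejected(self):
        with pytest.raises(ValueError):
            excess_profile(_dd([1, 1], 0.1), [_dd([1, 1], 0.2)])


def brute_force_first_intersection(e, edges):
    """Direct evaluation of the sign-run rule."""
    e = list(e)
    i = 0
    while i < len(e) and e[i] == 0:
        i += 1
    if i == len(e):
        return None, 0.0, "none"
    direction = 1.0 if e[i] > 0 else -1.0
    j = i
    while j < len(e) and np.sign(e[j]) == direction:
        j += 1
    return float(edges[j]), float(sum(e[:j])), ("positive" if direction > 0 else "negative")


class TestFirstIntersection:
    def test_positive_example(self):
        x0, a, d = first_intersection_and_mass([2, 1, -1, 0.5], np.arange(5) * 0.1)
        assert x0 == pytest.approx(0.2)
        assert a == pytest.approx(3.0)
        assert d == "positive"

    def test_negative_example(self):
        x0, a, d = first_intersection_and_mass([-2, -1, 3], np.arange(4) * 0.1)
        assert x0 == pytest.approx(0.2)
        assert a == pytest.approx(-3.0)
        assert d == "negative"

    def test_leading_zeros_skipped(self):
        x0, a, d = first_intersection_and_mass([0, 0, -1, 1], np.arange(5) * 0.1)
        assert d == "negative"
        assert x0 == pytest.approx(0.3)
        assert a == pytest.approx(-1.0)

    def test_all_zero(self):
        x0, a, d = first_intersection_and_mass([0.0, 0.0], np.arange(3) * 0.1)
        assert x0 is None and a == 0.0 and d == "none"

    def test_no_sign_change_runs_to_last_edge(self):
        x0, a, _ = first_intersection_and_mass([1.0, 2.0], np.arange(3) * 0.1)
        assert x0 == pytest.approx(0.2)
        assert a == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=12))
    def test_matches_brute_force(self, values):
        e = np.array(values, dtype=float)
        edges = np.arange(len(e) + 1) * 0.1
        assert first_intersection_and_mass(e, edges) == brute_force_first_intersection(e, edges)


class TestControls:
    def test_counts_conserved_and_deterministic(self, default_layout, default_rois):
        tumor = default_layout.tumor_polygon()
        c1 = simulate_controls(tumor, 200, default_rois, "lumen", n_reps=10, seed=3)
        c2 = simulate_controls(tumor, 200, default_rois, "lumen", n_reps=10, seed=3)
        for a, b in zip(c1, c2):
            assert a.counts.sum() == 200
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_mean_converges_to_strip_areas(self, default_layout, default_rois):
        """Mean control histogram approaches the geometric strip-area expectation."""
        tumor = default_layout.tumor_polygon()
        ctrls = simulate_controls(tumor, 1000, default_rois, "lumen", bin_width=0.5,
                                  n_reps=200, seed=4)
        mean = np.mean([c.counts for c in ctrls], axis=0)
        expected = 1000 / 10.0  # uniform depth: each 0.5 mm strip holds 1/10 of points
        np.testing.assert_allclose(mean, expected, rtol=0.05)

    def test_zero_points_flagged(self, default_layout, default_rois):
        with pytest.raises(DegenerateInputError):
            simulate_controls(default_layout.tumor_polygon(), 0, default_rois, "lumen")


class TestSignificance:
    def test_controls_identical_to_observed(self):
        obs = _dd([5, 3, 2])
        mass, a_i, ci, sig, p = excess_significance(obs, [obs] * 50, 0.1)
        assert mass == 0.0
        assert ci[0] <= 0.0 <= ci[1]
        assert not sig
        assert p == 1.0

    def test_mean_of_per_control_masses_equals_mass(self, default_layout, default_rois):
        pat = generate_csr_points(default_layout.tumor_polygon(), 30.0, seed=5)
        prof = excess_analysis(pat, default_rois, "lumen", seed=6)
        assert prof.mass == pytest.approx(prof.per_control_mass.mean(), rel=1e-12)

    def test_few_controls_warns(self):
        obs = _dd([5, 3])
        with pytest.warns(UserWarning):
            excess_significance(obs, [_dd([4, 4]) for _ in range(10)], 0.1)


class TestEndToEnd:
    def test_zero_sum_invariant(self, default_layout, default_rois):
        pat = generate_csr_points(default_layout.tumor_polygon(), 50.0, seed=7)
        prof = excess_analysis(pat, default_rois, "adjacent", seed=8)
        assert abs(prof.excess.sum()) <= 1e-9 * pat.n_points

    def test_belt_recovery_single_sample(self, default_layout, default_rois):
        pat, planted = generate_belt_pattern(
            default_layout, BeltSpec(80, 1.2, 4.0, "lumen", seed=9)
        )
        prof = excess_analysis(pat, default_rois, "lumen", seed=10)
        assert prof.significant and prof.direction == "positive"
        assert abs(prof.x0 - 1.2) <= 0.1 + 0.2  # bin width + 0.2 mm
        assert abs(prof.excess_corrected - planted) / planted < 0.15

    def test_monotone_power_in_enrichment(self, default_layout, default_rois):
        """Detection rate is non-decreasing in the enrichment factor k."""
        rates = []
        for k in (1.0, 2.0, 4.0):
            hits = 0
            for s in range(25):
                pat, _ = generate_belt_pattern(
                    default_layout, BeltSpec(30, 1.0, k, "lumen", seed=int(100 * k) + s)
                )
                prof = excess_analysis(pat, default_rois, "lumen", n_controls=50,
                                       seed=1000 + s)
                hits += prof.significant and prof.direction == "positive"
            rates.append(hits / 25)
        assert rates[0] <= rates[1] + 0.1  # k = 1 is null-level
        assert rates[1] <= rates[2]
        assert rates[2] >= 0.9

    def test_too_few_points_not_evaluable(self, default_rois):
        pat = PointPattern(np.array([[5.0, 3.0], [5.1, 3.1]]))
        with pytest.raises(DegenerateInputError):
            excess_analysis(pat, default_rois, "lumen", seed=0)

    def test_shared_controls_reused_across_references(self, default_layout, default_rois):
        """Passing the same control draws to both references is supported."""
        from vesselbelt.synthetic import sample_uniform_in_polygon

        tumor = default_layout.tumor_polygon()
        pat = generate_csr_points(tumor, 30.0, seed=11)
        r = np.random.default_rng(12)
        ctrl_pts = [sample_uniform_in_polygon(tumor, pat.n_points, r) for _ in range(50)]
        p1 = excess_analysis(pat, default_rois, "lumen", control_points=ctrl_pts)
        p2 = excess_analysis(pat, default_rois, "lumen", control_points=ctrl_pts)
        np.testing.assert_array_equal(p1.per_control_mass, p2.per_control_mass)
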