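import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blinksim import IBIDensityClassifier, IBISample
from blinksim.density import (
    DensityEstimate,
    classify,
    estimate_density,
    find_peaks,
    match_peaks,
    select_bandwidth,
)
from blinksim.io import make_fixture


def brute_force_kde(xs, grid, h):
    """Direct double-sum evaluation of the Gaussian KDE definition."""
    out = np.zeros_like(grid)
    for x in xs:
        u = (grid - x) / h
        out += np.exp(-0.5 * u * u)
    return out / (len(xs) * h * math.sqrt(2.0 * math.pi))


class TestEstimateDensity:
    def test_matches_brute_force_double_sum(self, rng):
        xs = rng.uniform(0.5, 15.0, size=50)
        d = estimate_density(xs, bandwidth=0.4)
        expected = brute_force_kde(xs, d.grid, 0.4)
        assert np.abs(d.values - expected).max() < 1e-12

    def test_single_atom_sample_is_a_kernel_bump(self):
        xs = np.full(100, 5.0)
        d = estimate_density(xs, bandwidth=0.5)
        peak_value = 1.0 / (0.5 * math.sqrt(2 * math.pi))
        i = np.argmin(np.abs(d.grid - 5.0))
        assert d.values[i] == pytest.approx(peak_value, rel=1e-12)
        assert np.argmax(d.values) == i

    def test_interior_sample_integrates_to_one(self, rng):
        xs = rng.normal(9.0, 1.5, size=800)
        xs = xs[(xs > 3) & (xs < 17)]
        d = estimate_density(xs, bandwidth=0.3)
        assert d.integral() == pytest.approx(1.0, abs=1e-3)

    def test_translation_shifts_peaks(self, rng):
        xs = rng.normal(6.0, 0.8, size=1500)
        delta = 4.0
        p0 = find_peaks(estimate_density(xs, bandwidth=0.4))
        p1 = find_peaks(estimate_density(xs + delta, bandwidth=0.4))
        np.testing.assert_allclose(p1, p0 + delta, atol=0.005 + 1e-12)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            estimate_density(np.array([1.0]))

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.array([1.0, 2.0]), bandwidth=0.5, grid_step=0.1)


class TestSelectBandwidth:
    def test_normal_reference_equals_silverman(self, rng):
        xs = 10.0 + 2.0 * rng.standard_normal(1000)
        h = select_bandwidth(xs)
        silverman = (4.0 / 3.0) ** 0.2 * np.std(xs, ddof=1) * len(xs) ** -0.2
        assert h == pytest.approx(silverman, rel=1e-9)

    def test_curvature_variant_within_factor_two_of_silverman_on_gaussian(self, rng):
        xs = 10.0 + 2.0 * rng.standard_normal(1000)
        h = select_bandwidth(xs, method="curvature")
        silverman = 1.06 * np.std(xs, ddof=1) * len(xs) ** -0.2
        assert silverman / 2 < h < silverman * 2

    @pytest.mark.parametrize("method", ["normal_reference", "curvature"])
    def test_bandwidth_decreases_with_sample_size(self, rng, method):
        xs = 10.0 + 2.0 * rng.standard_normal(4000)
        h_small = select_bandwidth(xs[:1000], method=method)
        h_large = select_bandwidth(xs, method=method)
        assert h_large < h_small

    def test_constant_sample_falls_back_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="blinksim.density"):
            h = select_bandwidth(np.full(50, 3.0))
        assert h == 0.05
        assert any("falling back" in r.message for r in caplog.records)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.array([1.0, 2.0]), method="magic")


class TestFindPeaks:
    def test_flat_density_below_height_floor_has_no_peaks(self):
        grid = np.linspace(0, 20, 4001)
        d = DensityEstimate(grid=grid, values=np.full_like(grid, 0.05), bandwidth=1.0, n=100)
        assert find_peaks(d).size == 0

    def test_two_component_mixture_gives_two_peaks(self, rng):
        comps = rng.integers(0, 2, size=2000)
        xs = rng.normal(np.where(comps == 0, 2.0, 7.0), 0.2)
        peaks = find_peaks(estimate_density(xs, bandwidth=0.2))
        assert peaks.size == 2
        np.testing.assert_allclose(peaks, [2.0, 7.0], atol=0.2)

    def test_single_gaussian_gives_one_peak(self, rng):
        xs = rng.normal(5.0, 1.0, size=2000)
        peaks = find_peaks(estimate_density(xs))
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(5.0, abs=0.2)

    def test_plateau_reports_leftmost_point(self):
        grid = np.linspace(0, 20, 4001)
        values = np.zeros_like(grid)
        values[1000:1004] = 1.0  # flat top
        values[999] = 0.5
        values[1004] = 0.5
        d = DensityEstimate(grid=grid, values=values, bandwidth=1.0, n=100)
        peaks = find_peaks(d)
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(grid[1000])

    def test_admitted_peaks_satisfy_both_conditions(self, burst_bimodal_sample):
        _, sample = burst_bimodal_sample
        d = estimate_density(sample)
        peaks = find_peaks(d)
        vmin, vmax = d.values.min(), d.values.max()
        for p in peaks:
            v = d.values[np.argmin(np.abs(d.grid - p))]
            assert v > 0.1
            assert v > vmin + (vmax - vmin) / 4


class TestClassify:
    def test_low_occurrence_is_not_computable(self):
        report = classify(IBISample(intervals=np.array([1.0, 2.0])))  # 3 blinks
        assert report.modality == "not_computable"
        assert report.n_peaks == 0
        assert report.skew_label == "n/a"
        assert report.median_ibi == pytest.approx(1.5)

    def test_early_peak_is_positively_skewed(self, rng):
        xs = np.clip(rng.normal(2.1, 0.5, size=1000), 0.05, None)
        report = classify(xs)
        assert report.modality == "unimodal"
        assert report.peaks[0] < 10
        assert report.skew_label == "positively_skewed"

    def test_late_peak_is_not_positively_skewed(self, rng):
        xs = rng.normal(14.0, 1.0, size=1000)
        report = classify(xs)
        assert report.modality == "unimodal"
        assert report.skew_label == "not_positively_skewed"

    def test_bimodal_skew_not_applicable(self, rng):
        sample, _ = make_fixture("bimodal", 2000, seed=7)
        report = classify(sample)
        assert report.modality == "bimodal"
        assert report.skew_label == "n/a"

    def test_pure_function_of_inputs(self, burst_bimodal_sample):
        _, sample = burst_bimodal_sample
        a = classify(sample)
        b = classify(sample)
        assert a.to_dict() == b.to_dict()

    def test_sklearn_estimator_exposes_fitted_report(self, rng):
        sample, means = make_fixture("bimodal", 2000, seed=7)
        clf = IBIDensityClassifier().fit(sample)
        assert clf.modality_ == "bimodal"
        assert clf.n_peaks_ == 2
        np.testing.assert_allclose(clf.peaks_, means, atol=0.3)
        assert clf.density_.bandwidth == clf.bandwidth_
        # sklearn param plumbing
        assert IBIDensityClassifier(bandwidth=0.3).get_params()["bandwidth"] == 0.3


class TestMatchPeaks:
    def test_within_tolerance_matches(self):
        assert match_peaks([0.49, 5.51], [0.5, 5.5]) is True

    def test_outside_tolerance_rejected(self):
        assert match_peaks([0.54, 5.5], [0.5, 5.5]) is False

    def test_cardinality_mismatch_rejected(self):
        assert match_peaks([0.5], [0.5, 5.5]) is False

    @given(st.floats(-0.024, 0.024), st.floats(-0.024, 0.024))
    def test_any_offsets_within_tolerance_match(self, d1, d2):
        assert match_peaks([0.5 + d1, 5.5 + d2], [0.5, 5.5]) is True
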