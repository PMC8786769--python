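"""Reflectivity metric definitions against hand computations and oracles."""

import math

import numpy as np
import pytest

from placidollt import metrics as rm
from placidollt.metrics import MetricsConfig, compute_all
from placidollt.preprocess import ProcessedROI

from _oracles import brute_metrics


def roi_from_values(values):
    """1-row ROI so set-semantics metrics can be fed plain pixel lists."""
    return ProcessedROI.from_grid(np.asarray(values, dtype=float)[None, :])


class TestSingleMetrics:
    def test_energy_is_mean_square(self):
        assert rm.energy(roi_from_values([10, 10])) == 100.0
        assert rm.energy(roi_from_values([1, 2, 3, 4])) == pytest.approx(30 / 4)

    def test_energy_dominates_squared_mean(self, random_roi_factory):
        roi = random_roi_factory(31, 17)
        assert rm.energy(roi) >= roi.values.mean() ** 2

    def test_relative_energy_normalisation(self):
        assert rm.relative_energy(roi_from_values([7, 7, 7])) == 1.0
        assert rm.relative_energy(roi_from_values([0, 4])) == pytest.approx(0.5)

    def test_relative_energy_undefined_on_black_roi(self):
        assert math.isnan(rm.relative_energy(roi_from_values([0, 0])))

    def test_entropy_values(self):
        assert rm.entropy(roi_from_values([128] * 100)) == 0.0
        assert rm.entropy(roi_from_values([3, 200])) == pytest.approx(math.log(2) / 2)
        # uniform over all 256 levels is the per-n maximum
        n = 256
        uniform = rm.entropy(roi_from_values(np.arange(256)))
        assert uniform == pytest.approx(math.log(256) / n)

    def test_sd_irregularity(self):
        assert rm.sd_irregularity(roi_from_values([50, 50])) == 0.0
        assert rm.sd_irregularity(roi_from_values([0, 2])) == pytest.approx(0.25)

    def test_sd_irregularity_equals_scaled_variance(self, random_roi_factory):
        roi = random_roi_factory(23, 29)
        expected = roi.values.var() / roi.pmax**2
        assert rm.sd_irregularity(roi) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("k", [2, 5, 20])
    def test_total_area_constant_grid(self, make_roi, k):
        c = 30.0
        roi = make_roi(np.full((k, k), c))
        assert rm.total_area(roi) == pytest.approx(c * (k - 1) ** 2 / k**2)

    def test_total_area_single_cell(self, make_roi):
        roi = make_roi([[0.0, 0.0], [0.0, 4.0]])
        assert rm.total_area(roi) == pytest.approx(0.25)

    def test_total_area_approaches_mean_on_large_grids(self, rng):
        k = 120
        grid = rng.integers(0, 256, size=(k, k)).astype(float)
        roi = ProcessedROI.from_grid(grid)
        assert abs(rm.total_area(roi) - grid.mean()) <= 2 / k * grid.mean()

    def test_total_area_undefined_below_four_pixels(self, make_roi):
        assert math.isnan(rm.total_area(roi_from_values([1, 2, 3])))

    def test_basic_stats_examples(self):
        stats = rm.basic_stats(roi_from_values([0, 0, 255]))
        assert stats["mean"] == pytest.approx(85.0)
        assert stats["mode"] == 0.0
        assert stats["median"] == 0.0
        assert stats["minimum"] == 0.0

    def test_constant_roi_stats(self):
        stats = rm.basic_stats(roi_from_values([50] * 9))
        assert (stats["mean"], stats["sd"], stats["median"]) == (50.0, 0.0, 50.0)
        assert (stats["mode"], stats["minimum"]) == (50.0, 50.0)
        assert math.isnan(stats["skewness"]) and math.isnan(stats["kurtosis"])

    def test_symmetric_histogram_has_zero_skewness(self):
        stats = rm.basic_stats(roi_from_values([10, 20, 30, 30, 40, 50]))
        assert stats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_median_even_n_takes_lower_central(self):
        assert rm.basic_stats(roi_from_values([1, 2, 3, 4]))["median"] == 2.0

    def test_mode_tie_breaks_to_lowest_level(self):
        assert rm.basic_stats(roi_from_values([5, 5, 9, 9, 7]))["mode"] == 5.0

    def test_histogram_counts(self):
        hist = rm.histogram(roi_from_values([0, 0, 255]))
        assert hist.counts[0] == 2 and hist.counts[255] == 1
        assert hist.counts.sum() == hist.n == 3


class TestComputeAll:
    def test_flat_field_composition(self):
        m = compute_all(roi_from_values([60] * 50))
        assert m.mean == 60.0 and m.sd == 0.0
        assert m.relative_energy == 1.0 and m.sd_irregularity == 0.0
        assert m.entropy == 0.0 and m.energy == 3600.0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(25):
            h, w = rng.integers(2, 40, size=2)
            grid = rng.integers(0, 256, size=(h, w)).astype(float)
            roi = ProcessedROI.from_grid(grid)
            got = compute_all(roi).as_dict()
            want = brute_metrics(grid.tolist())
            for name, val in want.items():
                if math.isnan(val):
                    assert math.isnan(got[name]), name
                else:
                    assert got[name] == pytest.approx(val, abs=1e-9), name

    def test_pixel_order_invariance(self, rng):
        values = rng.integers(0, 256, size=60).astype(float)
        a = compute_all(roi_from_values(values)).as_dict()
        b = compute_all(roi_from_values(rng.permutation(values))).as_dict()
        for name in rm.METRIC_NAMES:
            if name == "total_area":
                continue  # grid-dependent by design
            assert a[name] == pytest.approx(b[name], abs=1e-12)

    def test_normalisation_identities(self, random_roi_factory):
        roi = random_roi_factory(41, 37)
        m = compute_all(roi)
        assert m.relative_energy == pytest.approx(m.energy / roi.pmax**2, abs=1e-9)
        assert m.sd_irregularity == pytest.approx(m.sd**2 / roi.pmax**2, abs=1e-9)

    def test_scale_invariance_of_normalised_metrics(self, rng):
        values = rng.integers(1, 200, size=500).astype(float)
        m1 = compute_all(roi_from_values(values))
        alpha = 0.5
        m2 = compute_all(roi_from_values(alpha * values))
        assert m2.relative_energy == pytest.approx(m1.relative_energy, abs=1e-12)
        assert m2.sd_irregularity == pytest.approx(m1.sd_irregularity, abs=1e-12)
        assert m2.energy == pytest.approx(alpha**2 * m1.energy, rel=1e-12)
        assert m2.mean == pytest.approx(alpha * m1.mean, rel=1e-12)

    def test_constant_metrics_independent_of_roi_size(self):
        # dividing by n makes images comparable regardless of ROI size
        base = compute_all(roi_from_values([40] * 10)).as_dict()
        other = compute_all(roi_from_values([40] * 5000)).as_dict()
        for name in ("relative_energy", "sd_irregularity", "entropy", "energy"):
            assert base[name] == other[name]

    def test_pmax_full_mode_uses_255(self):
        roi = roi_from_values([0, 51])
        cfg = MetricsConfig(pmax_mode="full")
        assert rm.relative_energy(roi, cfg) == pytest.approx((51 / 255) ** 2 / 2)

    def test_entropy_pixel_mode_is_literal_formula(self):
        roi = roi_from_values([2, 4])
        cfg = MetricsConfig(entropy_mode="pixel")
        want = -(2 * math.log(2) + 4 * math.log(4)) / 2
        assert rm.entropy(roi, cfg) == pytest.approx(want)
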