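import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftstream import (
    ConfigurationError,
    FormatError,
    LabeledSeriesSet,
    calibrate_threshold,
    compute_D,
    fit_binning,
    histogram,
    kl_divergence,
)


def one_feature(vals):
    return LabeledSeriesSet(np.array(vals, dtype=float)[:, None], np.zeros(len(vals), dtype=int))


def kl_bruteforce(p, q):
    """Independent summation oracle for KL(p || q) in nats."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log(pi / qi)
    return total


def random_smoothed_pair(rng, n):
    p = rng.random(n) + 1e-3
    q = rng.random(n) + 1e-3
    return p / p.sum(), q / q.sum()


class TestFitBinning:
    def test_two_bin_edges(self):
        model = fit_binning(one_feature([0.0, 0.5, 1.0, 1.0]), n_bins=2)
        np.testing.assert_allclose(model.edges(0), [0.0, 0.5, 1.0])

    def test_degenerate_feature_gets_pseudo_range(self):
        model = fit_binning(one_feature([3.0, 3.0, 3.0]), n_bins=4)
        assert model.degenerate[0]
        np.testing.assert_allclose(model.mins[0], 2.5)
        np.testing.assert_allclose(model.maxs[0], 3.5)

    def test_range_and_widths(self):
        model = fit_binning(one_feature([-1.0, 4.0]), n_bins=10)
        np.testing.assert_allclose(model.maxs[0] - model.mins[0], 5.0)
        np.testing.assert_allclose(model.widths[0], 0.5)

    def test_equal_widths_invariant(self, rng):
        data = LabeledSeriesSet(rng.standard_normal((30, 5)), np.zeros(30, dtype=int))
        model = fit_binning(data, n_bins=7)
        for j in range(5):
            widths = np.diff(model.edges(j))
            np.testing.assert_allclose(widths, widths[0], atol=1e-12)

    def test_n_bins_floor(self):
        with pytest.raises(ConfigurationError):
            fit_binning(one_feature([0.0, 1.0]), n_bins=1)


class TestHistogram:
    def test_half_open_bins_last_closed(self):
        model = fit_binning(one_feature([0.0, 0.5, 1.0, 1.0]), n_bins=2, epsilon=0.0)
        dist = histogram(one_feature([0.0, 0.5, 1.0, 1.0]), model)
        np.testing.assert_allclose(dist.probs[0], [0.25, 0.75])

    def test_out_of_range_clips_to_edge_bins(self):
        model = fit_binning(one_feature([0.0, 1.0]), n_bins=2, epsilon=0.0)
        dist = histogram(one_feature([2.0, -3.0]), model)
        np.testing.assert_allclose(dist.probs[0], [0.5, 0.5])

    def test_smoothing_strictly_positive(self, rng):
        model = fit_binning(one_feature([0.0, 1.0]), n_bins=8, epsilon=1e-6)
        dist = histogram(one_feature([0.1, 0.1, 0.1]), model)
        assert (dist.probs > 0).all()
        np.testing.assert_allclose(dist.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_width_mismatch(self, toy_set):
        model = fit_binning(one_feature([0.0, 1.0]))
        with pytest.raises(FormatError):
            histogram(toy_set, model)


class TestKL:
    def test_identity_zero(self):
        assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_hand_computed(self):
        # 0.5 ln 2 + 0.5 ln(2/3)
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected, abs=1e-12)
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.14384, abs=1e-5)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(2, 12)
            p, q = random_smoothed_pair(rng, n)
            assert kl_divergence(p, q) == pytest.approx(kl_bruteforce(p, q), abs=1e-12)

    def test_zero_p_entries_contribute_zero(self):
        assert kl_divergence([0.0, 1.0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0], [0.5, 0.5])

    def test_negative_entries(self):
        with pytest.raises(ValueError):
            kl_divergence([-0.5, 1.5], [0.5, 0.5])

    def test_not_normalized(self):
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.2], [0.5, 0.5])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        p, q = random_smoothed_pair(rng, 8)
        assert kl_divergence(p, q) >= -1e-12


class TestComputeD:
    def make_dists(self, rng, s=40, l=6):
        data = LabeledSeriesSet(rng.standard_normal((s, l)), np.zeros(s, dtype=int))
        model = fit_binning(data, n_bins=5)
        return data, model

    def test_same_dataset_gives_zero(self, rng):
        data, model = self.make_dists(rng)
        dist = histogram(data, model)
        report = compute_D(dist, dist)
        assert report.D == 0.0
        assert (report.per_feature_kl == 0.0).all()

    def test_mean_of_per_feature_kls(self, rng):
        data, model = self.make_dists(rng)
        other = LabeledSeriesSet(
            rng.standard_normal((40, 6)) + 0.5, np.zeros(40, dtype=int)
        )
        p = histogram(data, model)
        q = histogram(other, model)
        report = compute_D(p, q)
        manual = np.mean(
            [kl_divergence(p.probs[j], q.probs[j]) for j in range(6)]
        )
        assert report.D == pytest.approx(manual, abs=1e-12)
        assert report.D == pytest.approx(report.per_feature_kl.mean(), abs=1e-15)

    def test_sample_order_invariance(self, rng):
        data, model = self.make_dists(rng)
        perm = LabeledSeriesSet(
            data.values[rng.permutation(40)], data.labels, data.class_names
        )
        assert compute_D(histogram(data, model), histogram(perm, model)).D == \
            compute_D(histogram(data, model), histogram(perm, model)).D
        # permuting the new dataset's rows leaves D unchanged
        other = LabeledSeriesSet(rng.standard_normal((40, 6)), np.zeros(40, dtype=int))
        d1 = compute_D(histogram(data, model), histogram(other, model)).D
        other_perm = LabeledSeriesSet(
            other.values[rng.permutation(40)], other.labels, other.class_names
        )
        d2 = compute_D(histogram(data, model), histogram(other_perm, model)).D
        assert d1 == d2

    def test_threshold_decision(self, rng):
        data, model = self.make_dists(rng)
        other = LabeledSeriesSet(
            rng.standard_normal((40, 6)) + 2.0, np.zeros(40, dtype=int)
        )
        report = compute_D(
            histogram(data, model), histogram(other, model), threshold=1e-6
        )
        assert report.update and report.D >= report.threshold

    def test_feature_count_mismatch(self, rng):
        data, model = self.make_dists(rng)
        short = LabeledSeriesSet(rng.standard_normal((10, 3)), np.zeros(10, dtype=int))
        model3 = fit_binning(short, n_bins=5)
        with pytest.raises(FormatError):
            compute_D(histogram(data, model), histogram(short, model3))

    def test_json_record_summary(self, rng):
        data, model = self.make_dists(rng)
        report = compute_D(histogram(data, model), histogram(data, model), threshold=0.5)
        rec = report.to_record()
        assert set(rec) == {"window", "D", "per_feature_kl_summary", "threshold", "update"}


class TestCalibrateThreshold:
    def test_deterministic(self, rng):
        data = LabeledSeriesSet(rng.standard_normal((60, 4)), np.zeros(60, dtype=int))
        model = fit_binning(data)
        t1 = calibrate_threshold(data, model, window_size=20, seed=5)
        t2 = calibrate_threshold(data, model, window_size=20, seed=5)
        assert t1 == t2

    def test_monotone_in_quantile(self, rng):
        data = LabeledSeriesSet(rng.standard_normal((60, 4)), np.zeros(60, dtype=int))
        model = fit_binning(data)
        lo = calibrate_threshold(data, model, window_size=20, quantile=0.5, seed=1)
        hi = calibrate_threshold(data, model, window_size=20, quantile=0.99, seed=1)
        assert hi >= lo > 0

    def test_null_concentrates_with_window_size(self, rng):
        data = LabeledSeriesSet(rng.standard_normal((400, 4)), np.zeros(400, dtype=int))
        model = fit_binning(data)
        small = calibrate_threshold(data, model, window_size=20, seed=2, n_boot=100)
        large = calibrate_threshold(data, model, window_size=300, seed=2, n_boot=100)
        assert large < small

    def test_validation(self, rng):
        data = LabeledSeriesSet(rng.standard_normal((20, 2)), np.zeros(20, dtype=int))
        model = fit_binning(data)
        with pytest.raises(ConfigurationError):
            calibrate_threshold(data, model, window_size=5, n_boot=5)
        with pytest.raises(ConfigurationError):
            calibrate_threshold(data, model, window_size=5, quantile=1.5)
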