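"""Outcome metrics: success counting, dimensionality, coactivation,
between-task variance, rate statistics."""

import numpy as np
import pytest

from eicpg.errors import InvalidParameterError
from eicpg.metrics import (between_task_variance, coactivation_index,
                           coactivation_matrix_mean, effective_dimensionality,
                           firing_rate_stats, performance_pct, stride_success)


def _bounds(n_strides, stride_len):
    return [(k * stride_len, (k + 1) * stride_len) for k in range(n_strides)]


class TestStrideSuccess:
    def test_perfect_output_scores_100(self):
        rng = np.random.default_rng(0)
        targets = rng.random((3, 40))
        success, rmse = stride_success(targets, targets, _bounds(4, 10))
        assert performance_pct(success) == 100.0
        assert np.allclose(rmse, 0)

    def test_constant_offset_equals_its_rmse(self):
        targets = np.zeros((2, 30))
        outputs = targets + 0.1
        success, rmse = stride_success(outputs, targets, _bounds(3, 10))
        assert np.allclose(rmse, 0.1)
        assert performance_pct(success) == 0.0

    def test_partial_success_counted_exactly(self):
        """3 of 4 evaluated cells matching gives 75%."""
        targets = np.zeros((2, 30))
        outputs = np.zeros((2, 30))
        outputs[1, 20:30] = 0.2  # one muscle fails in the last stride
        success, _ = stride_success(outputs, targets, _bounds(3, 10))
        assert success.shape == (2, 2)  # first stride excluded
        assert performance_pct(success) == 75.0

    def test_first_stride_excluded_by_default(self):
        targets = np.zeros((1, 20))
        outputs = np.zeros((1, 20))
        outputs[0, :10] = 1.0  # failure confined to the transient stride
        success, _ = stride_success(outputs, targets, _bounds(2, 10))
        assert performance_pct(success) == 100.0

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(InvalidParameterError):
            stride_success(np.zeros((2, 10)), np.zeros((2, 12)), _bounds(1, 10))

    def test_invariant_to_muscle_and_stride_permutation(self):
        rng = np.random.default_rng(1)
        targets = rng.random((4, 50))
        outputs = targets + rng.normal(0, 0.05, targets.shape)
        s1, _ = stride_success(outputs, targets, _bounds(5, 10))
        perm = rng.permutation(4)
        s2, _ = stride_success(outputs[perm], targets[perm], _bounds(5, 10))
        assert performance_pct(s1) == performance_pct(s2)


class TestEffectiveDimensionality:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 100)
        data = np.outer([1.0, 2.0, -0.5], t)
        assert effective_dimensionality(data) == 1

    def test_two_orthogonal_equal_variance_components(self):
        t = np.linspace(0, 4 * np.pi, 400)
        data = np.stack([np.sin(t), np.cos(t)])
        assert effective_dimensionality(data) == 2

    def test_isotropic_noise_fills_all_dimensions(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(50, 5000))
        assert effective_dimensionality(data) >= 48

    def test_constant_data_is_zero_dimensional(self):
        assert effective_dimensionality(np.ones((5, 20))) == 0

    def test_bounded_by_matrix_rank(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 40))
        assert effective_dimensionality(data) <= 6

    def test_monotone_in_variance_threshold(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(10, 500)) * np.arange(1, 11)[:, None]
        dims = [effective_dimensionality(data, th) for th in (0.5, 0.9, 0.99)]
        assert dims == sorted(dims)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            effective_dimensionality(np.zeros((3, 1)))


class TestCoactivationIndex:
    def test_identical_signals_give_one(self):
        y = np.abs(np.sin(np.linspace(0, 7, 200))) + 0.1
        assert coactivation_index(y, y) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        y1 = np.array([1.0, 1.0, 0.0, 0.0])
        y2 = np.array([0.0, 0.0, 1.0, 1.0])
        assert coactivation_index(y1, y2) == pytest.approx(0.0)

    def test_hand_computed_ratio(self):
        """After max-normalization b = (0.5, 0.5, 1): mean of (2/3, 2/3, 1)."""
        a = np.array([1.0, 1.0, 1.0])
        b = np.array([0.5, 0.5, 1.0])
        assert coactivation_index(a, b) == pytest.approx((2 / 3 + 2 / 3 + 1) / 3)

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        y1, y2 = rng.random(100), rng.random(100)
        assert coactivation_index(y1, y2) == pytest.approx(
            coactivation_index(y2, y1))
        assert coactivation_index(3.0 * y1, y2) == pytest.approx(
            coactivation_index(y1, 0.2 * y2))

    def test_all_zero_signal_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            val = coactivation_index(np.zeros(10), np.ones(10))
        assert np.isnan(val)

    def test_pairwise_mean_over_channels(self):
        y = np.stack([np.ones(20), np.ones(20), np.zeros(20) + 1.0])
        assert coactivation_matrix_mean(y) == pytest.approx(1.0)


class TestBetweenTaskVariance:
    def _setup(self, offsets):
        stride = np.zeros((1, 10))
        outputs = np.concatenate(
            [stride + off for off in [0.0] + list(offsets)], axis=1)
        n = 1 + len(offsets)
        bounds = _bounds(n, 10)
        labels = ["t0"] + [f"t{k}" for k in range(len(offsets))]
        return outputs, bounds, labels

    def test_identical_tasks_give_zero(self):
        outputs, bounds, _ = self._setup([0.0, 0.0, 0.0])
        labels = ["x", "a", "b", "c"]
        assert between_task_variance(outputs, bounds, labels) == pytest.approx(0.0)

    def test_constant_offsets_give_population_variance(self):
        """Task means at {0, 1, 2} give variance 2/3 everywhere."""
        outputs, bounds, labels = self._setup([0.0, 1.0, 2.0])
        assert between_task_variance(outputs, bounds, labels) == pytest.approx(2 / 3)

    def test_quadratic_scaling(self):
        outputs, bounds, labels = self._setup([0.0, 1.0, 2.0])
        v1 = between_task_variance(outputs, bounds, labels)
        v3 = between_task_variance(3.0 * outputs, bounds, labels)
        assert v3 == pytest.approx(9.0 * v1)

    def test_no_strides_rejected(self):
        with pytest.raises(InvalidParameterError):
            between_task_variance(np.zeros((1, 10)), _bounds(1, 10), ["a"])


class TestFiringRateStats:
    def test_constant_rates(self):
        stats = firing_rate_stats(np.full((5, 30), 0.4))
        assert stats.rate_mean == pytest.approx(0.4)
        assert stats.rate_network_variance == pytest.approx(0.0)
        assert stats.rate_skewness == 0.0

    def test_symmetric_rates_have_zero_skew(self):
        rates = np.linspace(0.0, 1.0, 101)[:, None] * np.ones((1, 10))
        stats = firing_rate_stats(rates)
        assert stats.rate_skewness == pytest.approx(0.0, abs=1e-10)

    def test_input_statistics_reported(self):
        rng = np.random.default_rng(6)
        x = rng.normal(-1.0, 2.0, size=(200, 50))
        stats = firing_rate_stats(np.zeros((200, 50)) + 0.1, x)
        assert stats.input_mean == pytest.approx(-1.0, abs=0.1)
        assert stats.input_network_variance == pytest.approx(4.0, rel=0.15)

    def test_pooled_vs_per_neuron_skew_option(self):
        rng = np.random.default_rng(7)
        rates = rng.beta(0.5, 2.0, size=(100, 200))
        pooled = firing_rate_stats(rates).rate_skewness
        per_neuron = firing_rate_stats(rates, pooled_skew=False).rate_skewness
        assert pooled > 0
        assert pooled != per_neuron
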