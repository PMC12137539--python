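"""Target-signal generation, assembly protocol, and serialization."""

import numpy as np
import pytest

from eicpg.errors import InvalidParameterError
from eicpg.metrics import effective_dimensionality
from eicpg.targets import (ACTIVITY_PERIODS, TRIM_SAMPLES, _lowpass,
                           assemble_signal, load_external_targets,
                           primitive_patterns, save_patterns,
                           synthetic_muscle_targets)


class TestPrimitivePatterns:
    def test_bump_peaks_ordered_across_cycle(self):
        pat = primitive_patterns(1.2)
        argmaxes = pat.channels.argmax(axis=1)
        assert list(argmaxes) == sorted(argmaxes)
        assert pat.channels.shape[0] == 5

    @pytest.mark.parametrize("speed", [0.2, 2.1, -1.0])
    def test_out_of_range_speed_rejected(self, speed):
        with pytest.raises(InvalidParameterError):
            primitive_patterns(speed)

    def test_speed_frequency_map_monotone(self):
        periods = [primitive_patterns(s).period for s in (0.3, 1.0, 2.0)]
        assert periods[0] > periods[1] > periods[2]

    def test_bump_integral_scales_with_period(self):
        """At fixed cycle shape, the time integral is proportional to period."""
        slow, fast = primitive_patterns(0.4), primitive_patterns(1.8)
        int_slow = slow.channels[0].sum() / slow.sample_rate
        int_fast = fast.channels[0].sum() / fast.sample_rate
        assert int_slow / int_fast == pytest.approx(slow.period / fast.period,
                                                    rel=0.02)


class TestSyntheticMuscleTargets:
    def test_seventeen_channels_in_unit_range(self):
        pats = synthetic_muscle_targets(seed=0)
        assert set(pats) == set(ACTIVITY_PERIODS)
        for pat in pats.values():
            assert pat.channels.shape[0] == 17
            assert pat.channels.min() >= 0.0
            assert pat.channels.max() <= 1.0

    def test_deterministic_given_seed(self):
        a = synthetic_muscle_targets(seed=5)
        b = synthetic_muscle_targets(seed=5)
        for act in a:
            assert np.array_equal(a[act].channels, b[act].channels)

    def test_low_dimensional_structure(self):
        """99% of target variance within at most primitives + activities PCs."""
        pats = synthetic_muscle_targets(seed=0)
        data = np.concatenate([p.channels for p in pats.values()], axis=1)
        assert effective_dimensionality(data) <= 8

    def test_activities_mutually_distinguishable(self):
        """Pairwise RMS difference > 0.05 on at least half the channels."""
        pats = synthetic_muscle_targets(seed=0)
        grid = np.linspace(0, 1, 101)
        resampled = {}
        for act, pat in pats.items():
            src = np.linspace(0, 1, pat.channels.shape[1])
            resampled[act] = np.stack(
                [np.interp(grid, src, ch) for ch in pat.channels])
        acts = list(resampled)
        for i in range(len(acts)):
            for j in range(i + 1, len(acts)):
                rms = np.sqrt(np.mean(
                    (resampled[acts[i]] - resampled[acts[j]])**2, axis=1))
                assert np.sum(rms > 0.05) >= 17 / 2

    def test_periods_are_activity_specific(self):
        pats = synthetic_muscle_targets(seed=0)
        periods = [p.period for p in pats.values()]
        assert len(set(periods)) == 3


class TestAssembleSignal:
    @pytest.fixture
    def patterns(self):
        return synthetic_muscle_targets(seed=1)

    def test_train_has_15_strides_in_activity_blocks(self, patterns):
        sig = assemble_signal(patterns, "train")
        assert sig.n_strides == 15
        # five consecutive strides per activity
        for k in range(0, 15, 5):
            assert len(set(sig.activities[k:k + 5])) == 1

    def test_test_has_21_interleaved_strides(self, patterns):
        sig = assemble_signal(patterns, "test", seed=3)
        assert sig.n_strides == 21
        counts = {a: sig.activities.count(a) for a in patterns}
        assert all(c == 7 for c in counts.values())

    def test_shuffle_depends_on_seed_only(self, patterns):
        a = assemble_signal(patterns, "test", seed=3)
        b = assemble_signal(patterns, "test", seed=3)
        c = assemble_signal(patterns, "test", seed=4)
        assert a.activities == b.activities
        assert a.activities != c.activities

    def test_invalid_mode_rejected(self, patterns):
        with pytest.raises(InvalidParameterError):
            assemble_signal(patterns, "validate")

    def test_trimmed_length_accounting(self, patterns):
        sig = assemble_signal(patterns, "train")
        stride_len = sum(patterns[a].n_samples for a in sig.activities)
        expected = stride_len + (15 - 1) - 2 * TRIM_SAMPLES  # gaps minus trim
        assert sig.signal.shape[1] == expected
        assert len(sig.input_wave) == expected

    def test_gap_sample_is_neighbour_midpoint(self, patterns):
        """The drive wave (not filtered) exposes the interpolation rule."""
        sig = assemble_signal(patterns, "train")
        (a0, b0), (a1, b1) = sig.stride_bounds[:2]
        gap = b0  # single sample between stride 0 and stride 1
        assert a1 == b0 + 1
        mid = 0.5 * (sig.input_wave[gap - 1] + sig.input_wave[gap + 1])
        assert sig.input_wave[gap] == pytest.approx(mid)

    def test_drive_phase_resets_at_stride_onset(self, patterns):
        sig = assemble_signal(patterns, "test", seed=0)
        for (start, _), act in list(zip(sig.stride_bounds, sig.activities))[1:]:
            # every stride starts at U = 1 rising
            assert sig.input_wave[start] == pytest.approx(1.0)
            assert sig.input_wave[start + 1] > 1.0

    def test_filter_passband_and_zero_phase(self):
        t = np.arange(2000) / 200.0
        raw = np.sin(2 * np.pi * 1.0 * t)
        filt = _lowpass(raw, 200.0)
        # 1 Hz passes with < 1% amplitude change
        assert np.max(np.abs(filt)) == pytest.approx(1.0, abs=0.01)
        # zero-phase: cross-correlation peak at zero lag
        xc = np.correlate(filt - filt.mean(), raw - raw.mean(), mode="full")
        assert abs(int(np.argmax(xc)) - (len(raw) - 1)) == 0


class TestSerialization:
    def test_hdf5_roundtrip_bit_identical(self, tmp_path):
        pats = synthetic_muscle_targets(seed=2)
        path = tmp_path / "targets.h5"
        save_patterns(pats, path)
        loaded = load_external_targets(path)
        for act in pats:
            assert np.array_equal(pats[act].channels, loaded[act].channels)
            assert loaded[act].period == pats[act].period

    def test_csv_roundtrip(self, tmp_path):
        pats = synthetic_muscle_targets(seed=2)
        save_patterns(pats, tmp_path / "targets.csv")
        loaded = load_external_targets(tmp_path / "targets_meta.json")
        for act in pats:
            assert np.allclose(pats[act].channels, loaded[act].channels)

    def test_missing_file_fails_cleanly(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_external_targets(tmp_path / "absent.h5")

    def test_out_of_range_values_warn_and_clip(self, tmp_path):
        pats = synthetic_muscle_targets(seed=2)
        act = next(iter(pats))
        pats[act].channels = pats[act].channels + 0.5  # push above 1
        save_patterns(pats, tmp_path / "bad.h5")
        with pytest.warns(UserWarning, match="clipping"):
            loaded = load_external_targets(tmp_path / "bad.h5")
        assert loaded[act].channels.max() <= 1.0
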