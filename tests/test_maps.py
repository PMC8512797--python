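import math

import numpy as np
import pytest

from hdemg import (
    ActivationMap,
    ConfigurationError,
    EMGRecording,
    GridLayout,
    NormalizationError,
    TrialWindow,
    UndefinedFeatureError,
    build_map,
    coefficient_of_variation,
    differential_intensity,
    intensity,
    mean_rms,
    modified_entropy,
)

FS = 1000.0


def _map(values, layout, normalized=False):
    return ActivationMap.from_channels(np.asarray(values, float), layout, normalized=normalized)


class TestBuildMap:
    def test_constant_channel_rms_is_its_magnitude(self, tiny_layout):
        rec = EMGRecording(np.full((1000, 6), -2.0), FS, tiny_layout)
        m = build_map(rec, TrialWindow(0, 500))
        np.testing.assert_allclose(m.valid_values, 2.0)

    def test_sinusoid_over_whole_cycles_gives_amplitude_over_sqrt2(self, tiny_layout):
        t = np.arange(500) / FS  # 0.5 s = 25 whole cycles at 50 Hz
        tone = 3.0 * np.sin(2 * np.pi * 50 * t)
        rec = EMGRecording(np.tile(tone[:, None], (1, 6)), FS, tiny_layout)
        m = build_map(rec, TrialWindow(0, 500))
        np.testing.assert_allclose(m.valid_values, 3.0 / math.sqrt(2), rtol=1e-12)

    def test_two_sample_window_matches_hand_arithmetic(self, tiny_layout):
        rec = EMGRecording(np.tile([[3.0], [4.0]], (1, 6)), FS, tiny_layout)
        m = build_map(rec, TrialWindow(0, 2))
        np.testing.assert_allclose(m.valid_values, math.sqrt(12.5))

    def test_masked_electrode_stays_absent(self, default_layout, rng):
        rec = EMGRecording(rng.standard_normal((600, 31)), FS, default_layout)
        m = build_map(rec, TrialWindow(0, 500))
        assert np.isnan(m.values[0, 3])
        assert m.valid_values.shape == (31,)

    def test_window_beyond_recording_rejected(self, tiny_layout):
        rec = EMGRecording(np.zeros((100, 6)), FS, tiny_layout)
        with pytest.raises(ConfigurationError):
            build_map(rec, TrialWindow(0, 200))

    def test_empty_window_cannot_be_constructed(self):
        with pytest.raises(ConfigurationError):
            TrialWindow(100, 100)


class TestIntensity:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10.0] * 6, 1.0),
            ([1.0] * 6, 0.0),
        ],
    )
    def test_uniform_maps(self, tiny_layout, values, expected):
        assert intensity(_map(values, tiny_layout)) == pytest.approx(expected)

    def test_four_channel_hand_computed_mean(self):
        layout = GridLayout(n_rows=2, n_cols=2, missing=frozenset())
        assert intensity(_map([1, 2, 3, 4], layout)) == pytest.approx(
            math.log10(2.5), rel=1e-12
        )

    def test_all_zero_map_is_undefined(self, tiny_layout):
        with pytest.raises(UndefinedFeatureError):
            intensity(_map([0.0] * 6, tiny_layout))


class TestDifferentialIntensity:
    def test_identical_channels_floor_with_flag(self, tiny_layout, rng):
        tone = rng.standard_normal(600)
        rec = EMGRecording(np.tile(tone[:, None], (1, 6)), FS, tiny_layout)
        di = differential_intensity(rec, TrialWindow(0, 500))
        assert di.floored
        assert di.value <= math.log10(1e-11)

    def test_constant_offset_pair_rms_is_the_offset(self):
        # 2x1 grid: a single fiber pair whose signals differ by a constant
        layout = GridLayout(n_rows=2, n_cols=1, missing=frozenset())
        base = np.zeros(500)
        samples = np.column_stack([base + 5.0, base + 2.0])  # offset d = 3
        rec = EMGRecording(samples, FS, layout)
        di = differential_intensity(rec, TrialWindow(0, 500))
        assert di.n_pairs == 1
        assert di.value == pytest.approx(math.log10(3.0), rel=1e-12)

    def test_matches_bruteforce_pair_enumeration(self, rng):
        # two-column toy grid, hand-enumerated pairs
        layout = GridLayout(n_rows=4, n_cols=2, missing=frozenset())
        samples = rng.standard_normal((400, 8))
        rec = EMGRecording(samples, FS, layout)
        window = TrialWindow(50, 350)
        pair_rms = []
        for c in range(2):
            for r in range(3):
                a = rec.channel(r, c)[50:350]
                b = rec.channel(r + 1, c)[50:350]
                pair_rms.append(np.sqrt(np.mean((a - b) ** 2)))
        expected = math.log10(sum(pair_rms) / len(pair_rms))
        di = differential_intensity(rec, window)
        assert di.n_pairs == 6
        assert di.value == pytest.approx(expected, rel=1e-12)

    def test_mean_of_logs_alternative(self, rng):
        layout = GridLayout(n_rows=3, n_cols=1, missing=frozenset())
        rec = EMGRecording(rng.standard_normal((300, 3)), FS, layout)
        window = TrialWindow(0, 300)
        d1 = rec.samples[:, 0] - rec.samples[:, 1]
        d2 = rec.samples[:, 1] - rec.samples[:, 2]
        expected = np.mean(
            [math.log10(np.sqrt(np.mean(d1**2))), math.log10(np.sqrt(np.mean(d2**2)))]
        )
        di = differential_intensity(rec, window, aggregate="mean_of_logs")
        assert di.value == pytest.approx(expected, rel=1e-12)

    def test_single_electrode_column_has_no_pairs(self):
        layout = GridLayout(n_rows=1, n_cols=3, missing=frozenset())
        rec = EMGRecording(np.zeros((100, 3)), FS, layout)
        with pytest.raises(ConfigurationError):
            differential_intensity(rec, TrialWindow(0, 100))


class TestModifiedEntropy:
    def test_28_equal_channels_reach_log2_28(self):
        layout = GridLayout(n_rows=7, n_cols=4, missing=frozenset())
        e = modified_entropy(_map([3.3] * 28, layout))
        assert e == pytest.approx(math.log2(28), rel=1e-12)
        assert round(e, 1) == 4.8

    def test_31_equal_channels_reach_log2_31(self, default_layout):
        e = modified_entropy(_map([0.7] * 31, default_layout))
        assert e == pytest.approx(math.log2(31), rel=1e-12)

    def test_single_active_channel_has_zero_entropy(self, tiny_layout):
        assert modified_entropy(_map([0, 0, 5.0, 0, 0, 0], tiny_layout)) == 0.0

    def test_two_equal_active_channels_give_one_bit(self, tiny_layout):
        e = modified_entropy(_map([2.0, 2.0, 0, 0, 0, 0], tiny_layout))
        assert e == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_map_is_undefined(self, tiny_layout):
        with pytest.raises(UndefinedFeatureError):
            modified_entropy(_map([0.0] * 6, tiny_layout))


class TestCoefficientOfVariation:
    def test_uniform_map_has_zero_cov(self, tiny_layout):
        assert coefficient_of_variation(_map([4.2] * 6, tiny_layout)) == 0.0

    def test_two_values_match_hand_arithmetic(self):
        layout = GridLayout(n_rows=2, n_cols=1, missing=frozenset())
        # values [1, 3]: sample SD sqrt(2), mean 2 -> 70.71%
        cov = coefficient_of_variation(_map([1.0, 3.0], layout))
        assert cov == pytest.approx(100 * math.sqrt(2) / 2, rel=1e-12)

    def test_population_sd_option(self):
        layout = GridLayout(n_rows=2, n_cols=1, missing=frozenset())
        cov = coefficient_of_variation(_map([1.0, 3.0], layout), ddof=0)
        assert cov == pytest.approx(50.0, rel=1e-12)

    def test_scale_invariance(self, tiny_layout, rng):
        values = rng.uniform(0.1, 5, 6)
        m = _map(values, tiny_layout)
        assert coefficient_of_variation(m.scaled(7.7)) == pytest.approx(
            coefficient_of_variation(m), rel=1e-12
        )

    def test_single_channel_is_undefined(self):
        layout = GridLayout(n_rows=1, n_cols=1, missing=frozenset())
        with pytest.raises(UndefinedFeatureError):
            coefficient_of_variation(_map([1.0], layout))

    def test_zero_mean_is_undefined(self, tiny_layout):
        with pytest.raises(UndefinedFeatureError):
            coefficient_of_variation(_map([0.0] * 6, tiny_layout))


class TestMeanRMS:
    def test_full_mvc_map_averages_one(self, tiny_layout):
        assert mean_rms(_map([1.0] * 6, tiny_layout, normalized=True)) == 1.0

    def test_half_active_at_20pct(self, tiny_layout):
        m = _map([0, 0, 0, 0.2, 0.2, 0.2], tiny_layout, normalized=True)
        assert mean_rms(m) == pytest.approx(0.1)

    def test_hand_computed_four_channel_mean(self):
        layout = GridLayout(n_rows=2, n_cols=2, missing=frozenset())
        m = _map([0.06, 0.08, 0.04, 0.06], layout, normalized=True)
        assert mean_rms(m) == pytest.approx(0.06, rel=1e-12)

    def test_unnormalized_map_rejected(self, tiny_layout):
        with pytest.raises(NormalizationError):
            mean_rms(_map([1.0] * 6, tiny_layout))
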