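import numpy as np
import pytest
from scipy import signal as sps

from hdemg import (
    ConfigurationError,
    DesignEffect,
    GridLayout,
    SimulationConfig,
    SourceTerritory,
    StudyDesign,
    generate_force_trace,
    generate_grid_emg,
    generate_mvc_trials,
    generate_study,
)
from hdemg.simulate import (
    DEFAULT_EFFECTS,
    clustering_to_spread,
    expected_channel_rms,
)


def _rms(x, axis=0):
    return np.sqrt(np.mean(np.asarray(x) ** 2, axis=axis))


class TestGenerateGridEMG:
    def test_zero_gain_zero_noise_gives_silence(self, default_layout):
        territory = SourceTerritory((3.5, 1.5), spread=2.0, gain=0.0)
        config = SimulationConfig(duration=1.0, territories=(territory,), noise_sd=0.0)
        rec = generate_grid_emg(config, default_layout)
        assert np.all(rec.samples == 0)

    def test_uniform_activation_rms_matches_analytic_weights(self, default_layout):
        config = SimulationConfig(duration=5.0, clustering=0.0, noise_sd=0.0, seed=11)
        rec = generate_grid_emg(config, default_layout)
        target = expected_channel_rms(config, default_layout)
        np.testing.assert_allclose(_rms(rec.samples), target, rtol=0.05)

    def test_rms_follows_quadrature_formula_with_noise(self, default_layout):
        config = SimulationConfig(duration=4.0, clustering=0.8, noise_sd=0.3, seed=7)
        rec = generate_grid_emg(config, default_layout)
        target = expected_channel_rms(config, default_layout)
        np.testing.assert_allclose(_rms(rec.samples), target, rtol=0.08)

    def test_deterministic_given_seed(self, default_layout):
        config = SimulationConfig(duration=1.0, seed=42)
        a = generate_grid_emg(config, default_layout)
        b = generate_grid_emg(config, default_layout)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self, default_layout):
        a = generate_grid_emg(SimulationConfig(duration=1.0, seed=1), default_layout)
        b = generate_grid_emg(SimulationConfig(duration=1.0, seed=2), default_layout)
        assert not np.array_equal(a.samples, b.samples)

    def test_channels_are_zero_mean_and_one_per_valid_electrode(self, default_layout):
        config = SimulationConfig(duration=3.0, seed=5)
        rec = generate_grid_emg(config, default_layout)
        assert rec.n_channels == 31
        assert rec.n_samples == 3000
        np.testing.assert_allclose(rec.samples.mean(axis=0), 0.0, atol=0.05)

    def test_out_of_band_power_below_one_percent(self, default_layout):
        config = SimulationConfig(duration=5.0, seed=9)
        rec = generate_grid_emg(config, default_layout)
        freqs, psd = sps.periodogram(rec.samples[:, 0], fs=rec.sampling_rate)
        out_of_band = (freqs < 10) | (freqs > 500)
        assert psd[out_of_band].sum() < 0.01 * psd.sum()

    def test_invalid_band_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(band=(10.0, 600.0), sampling_rate=1000.0)

    def test_territory_outside_grid_rejected(self, default_layout):
        territory = SourceTerritory((20.0, 0.0), spread=1.0, gain=1.0)
        config = SimulationConfig(territories=(territory,))
        with pytest.raises(ConfigurationError):
            generate_grid_emg(config, default_layout)


class TestClusteringKnob:
    def test_maps_linearly_onto_spread(self):
        s0 = clustering_to_spread(0.0)
        s1 = clustering_to_spread(1.0)
        s_half = clustering_to_spread(0.5)
        assert s0 > s1 > 0
        assert s_half == pytest.approx((s0 + s1) / 2)

    def test_uniform_end_gives_near_uniform_weights(self, default_layout):
        config = SimulationConfig(clustering=0.0, noise_sd=0.0)
        target = expected_channel_rms(config, default_layout)
        assert target.min() > 0.95 * target.max()

    def test_clustered_end_concentrates_weight(self, default_layout):
        config = SimulationConfig(clustering=1.0, noise_sd=0.0)
        target = expected_channel_rms(config, default_layout)
        assert target.min() < 0.01 * target.max()


class TestGenerateForceTrace:
    def test_threshold_crossed_at_onset_within_one_sample(self):
        config = SimulationConfig(duration=3.0, onset_time=1.0, force_plateau=100.0, seed=3)
        trace = generate_force_trace(config)
        first_above = int(np.flatnonzero(trace.force > 20.0)[0])
        assert abs(first_above - 1000) <= 1

    def test_low_plateau_never_exceeds_threshold(self):
        config = SimulationConfig(duration=3.0, onset_time=1.0, force_plateau=10.0, seed=3)
        trace = generate_force_trace(config)
        assert np.all(trace.force <= 20.0)

    def test_noiseless_preonset_samples_stay_below_threshold(self):
        config = SimulationConfig(
            duration=3.0, onset_time=1.5, force_plateau=200.0, force_noise_sd=0.0
        )
        trace = generate_force_trace(config)
        assert np.all(trace.force[:1500] <= 20.0)

    def test_rise_through_threshold_is_monotone(self):
        config = SimulationConfig(duration=3.0, onset_time=1.0, force_plateau=150.0, seed=8)
        trace = generate_force_trace(config)
        near = (trace.force > 5) & (trace.force < trace.force.max() * 0.9)
        idx = np.flatnonzero(near)
        assert np.all(np.diff(trace.force[idx[0] : idx[-1] + 1]) >= 0)

    def test_onset_too_close_to_end_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_force_trace(SimulationConfig(duration=1.2, onset_time=1.0))

    def test_deterministic_given_seed(self):
        config = SimulationConfig(duration=2.0, seed=6)
        np.testing.assert_array_equal(
            generate_force_trace(config).force, generate_force_trace(config).force
        )


class TestGenerateMVCTrials:
    def test_three_trials_of_five_seconds_by_default(self, default_layout):
        trials = generate_mvc_trials(default_layout, 1.0, seed=0)
        assert len(trials) == 3
        assert all(t.duration == pytest.approx(5.0) for t in trials)

    def test_per_channel_rms_equals_requested_amplitude(self, default_layout):
        trials = generate_mvc_trials(default_layout, 1.0, seed=0)
        for t in trials:
            np.testing.assert_allclose(_rms(t.samples), 1.0, rtol=1e-12)

    def test_per_channel_amplitude_vector_supported(self, tiny_layout):
        amp = np.array([1, 2, 3, 4, 5, 6.0])
        trials = generate_mvc_trials(tiny_layout, amp, seed=1, duration=2.0)
        np.testing.assert_allclose(_rms(trials[0].samples), amp, rtol=1e-12)

    def test_different_seeds_give_different_paths_same_rms(self, tiny_layout):
        a = generate_mvc_trials(tiny_layout, 2.0, seed=1, duration=2.0)[0]
        b = generate_mvc_trials(tiny_layout, 2.0, seed=2, duration=2.0)[0]
        assert not np.array_equal(a.samples, b.samples)
        np.testing.assert_allclose(_rms(a.samples), _rms(b.samples), rtol=1e-12)

    def test_non_positive_amplitude_rejected(self, tiny_layout):
        with pytest.raises(ConfigurationError):
            generate_mvc_trials(tiny_layout, 0.0)


class TestGenerateStudy:
    def test_one_participant_yields_18_bundles(self):
        design = StudyDesign(n_participants=1, duration=2.0, seed=1)
        study = generate_study(design)
        assert len(study.bundles) == 18

    def test_bundles_scale_with_participants(self):
        design = StudyDesign(n_participants=2, duration=2.0, seed=1)
        study = generate_study(design)
        assert len(study.bundles) == 36
        assert len(study.participants) == 2

    def test_each_bundle_covers_both_sides_with_shared_force(self):
        design = StudyDesign(n_participants=1, duration=2.0, seed=1)
        bundle = generate_study(design).bundles[0]
        assert set(bundle.recordings) == {"left", "right"}
        assert set(bundle.mvc_trials) == {"left", "right"}
        assert bundle.force.n_samples == bundle.recordings["left"].n_samples

    def test_identity_effect_table_makes_designs_exchangeable(self):
        identity = {code: DesignEffect() for code in DEFAULT_EFFECTS}
        design = StudyDesign(
            n_participants=1, duration=2.0, effect_table=identity, seed=2
        )
        study = generate_study(design)
        clusterings = {b.ground_truth["clustering"] for b in study.bundles}
        assert clusterings == {design.base_clustering}

    def test_deterministic_given_seed(self):
        design = StudyDesign(n_participants=1, duration=2.0, seed=9)
        a = generate_study(design).bundles[3]
        b = generate_study(design).bundles[3]
        np.testing.assert_array_equal(
            a.recordings["left"].samples, b.recordings["left"].samples
        )
        np.testing.assert_array_equal(a.force.force, b.force.force)

    def test_wrong_design_cardinality_rejected(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(designs=("HH", "HS"))

    def test_effect_table_must_cover_all_designs(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(effect_table={"HH": DesignEffect()})
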