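import numpy as np
import pytest
from scipy.signal import periodogram

from eitclean.artifacts import (
    CleaningConfig,
    DetectedEvent,
    clean_channel,
    clean_frames,
    correct_steps,
    detect_steps,
    drift_level_for_cutoff,
    remove_baseline_drift,
    remove_spikes,
)
from eitclean.imaging import N_CHANNELS, FrameSeries
from eitclean.metrics import prd, r_squared
from eitclean.simulate import (
    ArtifactSpec,
    BreathingSimConfig,
    artifact_vector,
    simulate_breathing,
    simulate_contaminated_dataset,
)

FS = 20.0


def breathing(seed=0, **kw):
    return simulate_breathing(BreathingSimConfig(seed=seed, **kw))


class TestDriftRemoval:
    def test_respiratory_band_passes_through(self):
        """A pure 0.25 Hz sine lies above the a_6 band and survives."""
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 0.25 * t)
        y = remove_baseline_drift(x, FS)
        assert 0.95 <= r_squared(x, y) <= 1.05

    def test_linear_ramp_is_removed(self):
        truth = breathing(seed=1)
        ramp = np.linspace(0.0, 2.0, truth.size)
        cont = truth + ramp
        y = remove_baseline_drift(cont, FS)
        assert prd(truth, y) <= 0.2 * prd(truth, cont)

    def test_zero_signal_stays_zero(self):
        assert np.max(np.abs(remove_baseline_drift(np.zeros(5000), FS))) == 0.0

    def test_drift_level_beyond_admissible_depth_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            remove_baseline_drift(np.ones(100), FS, CleaningConfig(drift_level=6))

    def test_output_is_near_zero_mean(self):
        y = remove_baseline_drift(breathing(seed=2) + 5.0, FS)
        assert abs(y.mean()) < 0.01

    def test_operator_is_drift_insensitive(self):
        """Adding an in-band drift changes the output by < 0.05 PRD."""
        x = breathing(seed=4)
        drift = artifact_vector(
            ArtifactSpec(kind="drift", amplitude=1.0, shape="sinusoidal",
                         drift_freq=0.02),
            x.size, FS,
        )
        delta = remove_baseline_drift(x + drift, FS) - remove_baseline_drift(x, FS)
        assert prd(x, x + delta) <= 0.05

    def test_cutoff_to_level_rule(self):
        assert drift_level_for_cutoff(20.0, 0.156) == 6
        with pytest.raises(ValueError):
            drift_level_for_cutoff(20.0, 0.0)


class TestStepDetection:
    def test_single_step_localized(self):
        spec = ArtifactSpec(kind="step", amplitude=1.0, onset=2500)
        _, cont, _ = simulate_contaminated_dataset(BreathingSimConfig(seed=0), [spec])
        events = detect_steps(cont)
        steps = [e for e in events if e.kind == "step"]
        assert len(steps) == 1
        assert abs(steps[0].location - 2500) <= 8

    def test_artifact_free_signal_yields_no_events(self):
        assert detect_steps(breathing(seed=3)) == []

    def test_two_steps_with_sign_correct_offsets(self):
        specs = [
            ArtifactSpec(kind="step", amplitude=1.0, onset=1000),
            ArtifactSpec(kind="step", amplitude=-0.8, onset=3000),
        ]
        _, cont, _ = simulate_contaminated_dataset(BreathingSimConfig(seed=0), specs)
        steps = [e for e in detect_steps(cont) if e.kind == "step"]
        assert len(steps) == 2
        assert steps[0].offset_estimate > 0
        assert steps[1].offset_estimate < 0
        assert abs(steps[0].location - 1000) <= 8
        assert abs(steps[1].location - 3000) <= 8

    def test_constant_signal_yields_no_events(self):
        assert detect_steps(np.full(2000, 2.5)) == []

    def test_spike_classified_as_transient(self):
        spec = ArtifactSpec(kind="spike", amplitude=1.5, width=3, count=5, seed=3)
        _, cont, _ = simulate_contaminated_dataset(BreathingSimConfig(seed=3), [spec])
        events = detect_steps(cont)
        assert events  # spikes are large enough to flag
        assert all(e.kind == "spike" for e in events)

    def test_false_positive_rate_on_clean_signals(self):
        """No events in >= 95 of 100 artifact-free simulations."""
        clean_runs = sum(
            1 for seed in range(100)
            if not detect_steps(breathing(seed=seed, noise_amplitude=0.05))
        )
        assert clean_runs >= 95

    def test_signal_shorter_than_windows_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_steps(np.ones(50))


class TestStepCorrection:
    def test_empty_event_list_is_identity(self):
        x = breathing(seed=1)
        assert np.array_equal(correct_steps(x, []), x)

    def test_correction_restores_signal(self):
        spec = ArtifactSpec(kind="step", amplitude=1.0, onset=2500)
        truth, cont, _ = simulate_contaminated_dataset(BreathingSimConfig(seed=1), [spec])
        corrected = correct_steps(cont, detect_steps(cont))
        assert prd(truth, corrected) <= 0.1 * prd(truth, cont)

    def test_offset_recovery_accuracy(self):
        """Median |offset error| over seeds well below the 0.1 tolerance."""
        errors = []
        for seed in range(5):
            spec = ArtifactSpec(kind="step", amplitude=1.0, onset=2500)
            _, cont, _ = simulate_contaminated_dataset(
                BreathingSimConfig(seed=seed), [spec]
            )
            steps = [e for e in detect_steps(cont) if e.kind == "step"]
            errors.append(abs(steps[0].offset_estimate - 1.0))
        assert np.median(errors) <= 0.1

    def test_event_outside_signal_rejected(self):
        ev = DetectedEvent(kind="step", location=100, support=(90, 110),
                           offset_estimate=1.0)
        with pytest.raises(ValueError, match="outside"):
            correct_steps(np.ones(50), [ev])


class TestSpikeRemoval:
    def test_spikes_suppressed(self):
        spec = ArtifactSpec(kind="spike", amplitude=1.5, width=3, count=5, seed=11)
        truth, cont, _ = simulate_contaminated_dataset(BreathingSimConfig(seed=11), [spec])
        out = remove_spikes(cont)
        assert prd(truth, out) <= 0.5 * prd(truth, cont)

    def test_artifact_free_signal_passes_through(self):
        x = breathing(seed=6)
        assert prd(x, remove_spikes(x)) <= 0.05

    def test_zero_global_mode_deletes_cardiac_band(self):
        """Zeroing d_1..d_4 wholesale removes the 1 Hz cardiac component."""
        x = breathing(seed=2)
        y = remove_spikes(x, CleaningConfig(spike_mode="zero_global"))
        f, p_in = periodogram(x, fs=FS)
        _, p_out = periodogram(y, fs=FS)
        band = (f >= 0.625) & (f <= 1.25)
        assert 1 - p_out[band].sum() / p_in[band].sum() > 0.8

    def test_never_increases_prd_on_simulation_family(self):
        for amplitude in (0.5, 1.5, 3.0):
            for seed in range(5):
                spec = ArtifactSpec(kind="spike", amplitude=amplitude,
                                    width=3, count=5, seed=seed)
                truth, cont, _ = simulate_contaminated_dataset(
                    BreathingSimConfig(seed=seed), [spec]
                )
                assert prd(truth, remove_spikes(cont)) <= prd(truth, cont)

    def test_invalid_level_range_rejected(self):
        with pytest.raises(ValueError, match="spike level"):
            remove_spikes(np.ones(64), CleaningConfig(spike_levels=(1, 6)))


class TestCleanChannel:
    def test_drift_stage_delegates_exactly(self):
        x = breathing(seed=1)
        y, events = clean_channel(x, FS, stages=("drift",))
        assert np.array_equal(y, remove_baseline_drift(x, FS))
        assert events == []

    def test_all_three_artifacts_cleaned(self):
        specs = [
            ArtifactSpec(kind="drift", amplitude=1.0, shape="sinusoidal",
                         drift_freq=0.02),
            ArtifactSpec(kind="step", amplitude=1.0, onset=2500),
            ArtifactSpec(kind="spike", amplitude=1.5, width=3, count=5, seed=8),
        ]
        truth, cont, _ = simulate_contaminated_dataset(BreathingSimConfig(seed=8), specs)
        y, events = clean_channel(cont, FS)
        assert prd(truth, y) <= 0.3 * prd(truth, cont)
        assert any(e.kind == "step" for e in events)

    def test_artifact_free_pass_through(self):
        """Steps/spikes leave a clean signal alone; the drift stage costs a
        small respiratory-band leakage (the a_6 filter rolls off at 0.156 Hz,
        not a brick wall), so the full pipeline is bounded looser."""
        x = breathing(seed=5)
        y_ss, _ = clean_channel(x, FS, stages=("step", "spike"))
        assert prd(x, y_ss) <= 0.05
        y_all, _ = clean_channel(x, FS)
        assert prd(x, y_all) <= 0.5
        assert 0.95 <= r_squared(x, y_all) <= 1.05

    def test_idempotence(self):
        specs = [ArtifactSpec(kind="step", amplitude=1.0, onset=2500)]
        _, cont, _ = simulate_contaminated_dataset(BreathingSimConfig(seed=9), specs)
        once, _ = clean_channel(cont, FS)
        twice, _ = clean_channel(once, FS)
        assert prd(once, twice) < 0.05

    def test_stages_preserve_length_and_finiteness(self):
        x = breathing(seed=10, n_samples=3000)
        for stages in (("drift",), ("step",), ("spike",), ("drift", "step", "spike")):
            y, _ = clean_channel(x, FS, stages=stages)
            assert y.shape == x.shape
            assert np.all(np.isfinite(y))

    def test_empty_stage_list_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            clean_channel(breathing(), FS, stages=())

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            clean_channel(breathing(), FS, stages=("median",))


class TestCleanFrames:
    def test_identical_channels_stay_identical(self):
        x = breathing(seed=1, n_samples=1500)
        frames = FrameSeries(np.tile(x[:, None], (1, N_CHANNELS)), fs=FS)
        cleaned, _ = clean_frames(frames, stages=("drift",))
        assert np.all(cleaned.data == cleaned.data[:, [0]])

    def test_artifact_on_some_channels_leaves_others_untouched(self):
        from eitclean.simulate import simulate_frame_series

        gains = np.zeros(N_CHANNELS)
        gains[:10] = 1.0
        cfg = BreathingSimConfig(seed=2, n_samples=1500, noise_amplitude=0.02)
        spec = ArtifactSpec(kind="step", amplitude=1.0, onset=750)
        truth, cont = simulate_frame_series(cfg, [spec], artifact_gains=gains)
        cleaned, events = clean_frames(cont, stages=("step",))
        untouched = cleaned.data[:, 10:] - cont.data[:, 10:]
        assert np.max(np.abs(untouched)) == 0.0
        assert set(events) <= set(range(10))

    def test_global_waveform_is_mean_of_channels(self):
        x = breathing(seed=3, n_samples=1500)
        data = np.tile(x[:, None], (1, N_CHANNELS)) * np.linspace(
            0.5, 1.5, N_CHANNELS
        )
        cleaned, _ = clean_frames(FrameSeries(data, fs=FS), stages=("drift",))
        assert np.allclose(cleaned.global_waveform(), cleaned.data.mean(axis=1))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="at least one frame"):
            FrameSeries(np.empty((0, N_CHANNELS)), fs=FS)

    def test_non_finite_entry_names_location(self):
        data = np.zeros((100, N_CHANNELS))
        data[7, 3] = np.inf
        with pytest.raises(ValueError, match="frame 7, channel 3"):
            FrameSeries(data, fs=FS)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"threshold_k": 0.0},
            {"step_offset_window": 0},
            {"spike_levels": (3, 2)},
            {"spike_mode": "adaptive"},
            {"drift_level": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CleaningConfig(**kwargs)

    def test_roundtrip_through_dict(self):
        cfg = CleaningConfig(threshold_k=4.0, spike_levels=(2, 3))
        assert CleaningConfig.from_dict(cfg.to_dict()) == cfg
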