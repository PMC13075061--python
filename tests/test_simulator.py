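import numpy as np
import pytest

from fmcwvitals import (
    MotionProfile,
    SceneConfig,
    derive_params,
    emulate_reference_monitor,
    generate_displacement,
    synthesize_capture,
)
from conftest import make_breathing_capture


class TestGenerateDisplacement:
    def test_dominant_frequency_matches_configured_rate(self, default_config):
        profile = MotionProfile(
            duration=60.0, respiration_rate=85.0, cardiac_amplitude_mm=0.0
        )
        truth = generate_displacement(profile, default_config)
        x = truth.displacement_m - truth.displacement_m.mean()
        freqs = np.fft.rfftfreq(x.size, 1.0 / default_config.ramp_rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert peak == pytest.approx(85.0 / 60.0, abs=freqs[1])

    def test_respiration_suppressed_during_apnea(self, default_config):
        profile = MotionProfile(
            duration=60.0,
            respiration_rate=85.0,
            cardiac_amplitude_mm=0.0,
            apnea_intervals=[(20.0, 34.0)],
        )
        truth = generate_displacement(profile, default_config)
        t = truth.timestamps
        inside = (t >= 20.0) & (t < 34.0)
        np.testing.assert_array_equal(
            truth.displacement_m[inside], profile.nominal_range_m
        )
        assert np.all(np.isnan(truth.true_rate.rate[inside]))
        assert np.all(np.isfinite(truth.true_rate.rate[~inside]))

    def test_seed_determinism(self, default_config):
        profile = MotionProfile(duration=30.0, motion_intervals=[(5.0, 15.0, 5.0)])
        a = generate_displacement(profile, default_config, seed=7)
        b = generate_displacement(profile, default_config, seed=7)
        np.testing.assert_array_equal(a.displacement_m, b.displacement_m)
        c = generate_displacement(profile, default_config, seed=8)
        assert not np.array_equal(a.displacement_m, c.displacement_m)

    def test_overlapping_apnea_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MotionProfile(duration=60.0, apnea_intervals=[(10.0, 25.0), (20.0, 30.0)])

    def test_interval_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            MotionProfile(duration=60.0, apnea_intervals=[(50.0, 70.0)])


class TestSynthesizeCapture:
    def test_static_scene_all_ramps_identical(self, iq_config):
        profile = MotionProfile(
            duration=2.0, respiration_amplitude_mm=0.0, cardiac_amplitude_mm=0.0
        )
        truth = generate_displacement(profile, iq_config)
        capture = synthesize_capture(
            iq_config, SceneConfig(clutter_targets=(), noise_sigma=0.0), truth
        )
        np.testing.assert_array_equal(
            capture.samples, np.broadcast_to(capture.samples[:1], capture.samples.shape)
        )

    def test_n_ramps_from_duration(self, default_config):
        truth, capture = make_breathing_capture(default_config, duration=10.0)
        assert capture.n_ramps == 320

    def test_phase_displacement_relation(self, iq_config, clean_scene):
        """Unwrapped DFT phase at the target bin tracks 4 pi x(t) / lambda."""
        truth, capture = make_breathing_capture(
            iq_config, duration=20.0, amplitude_mm=1.0, scene=clean_scene
        )
        lam = derive_params(iq_config).wavelength
        n = iq_config.samples_per_ramp
        spec = np.fft.fft(capture.samples[:, 0, :], axis=-1)
        t_ramp = n / iq_config.sampling_frequency
        beat = 2 * truth.displacement_m.mean() * iq_config.bandwidth / (
            299792458.0 * t_ramp
        )
        target_bin = int(round(beat / (iq_config.sampling_frequency / n)))
        phase = np.unwrap(np.angle(spec[:, target_bin]))
        expected = 4.0 * np.pi * truth.displacement_m / lam
        dev = (phase - phase.mean()) - (expected - expected.mean())
        assert np.max(np.abs(dev)) < 0.01

    def test_power_scales_with_squared_amplitude(self, iq_config, clean_scene):
        truth, cap1 = make_breathing_capture(iq_config, duration=5.0, scene=clean_scene)
        scene2 = SceneConfig(
            clutter_targets=(), noise_sigma=0.0, channel_gains=[2.0] * 4
        )
        cap2 = synthesize_capture(iq_config, scene2, truth)
        p1 = np.mean(np.abs(cap1.samples) ** 2)
        p2 = np.mean(np.abs(cap2.samples) ** 2)
        assert p2 / p1 == pytest.approx(4.0, rel=1e-2)

    def test_capture_determinism(self, default_config):
        profile = MotionProfile(duration=5.0)
        truth = generate_displacement(profile, default_config, seed=3)
        scene = SceneConfig(seed=3)
        a = synthesize_capture(default_config, scene, truth)
        b = synthesize_capture(default_config, scene, truth)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_out_of_span_target_rejected(self, default_config):
        profile = MotionProfile(duration=1.0, nominal_range_m=50.0)
        truth = generate_displacement(profile, default_config)
        with pytest.raises(ValueError, match="Nyquist"):
            synthesize_capture(
                default_config, SceneConfig(clutter_targets=()), truth
            )

    def test_i_only_is_real_part(self, default_config, iq_config, clean_scene):
        profile = MotionProfile(duration=2.0)
        truth = generate_displacement(profile, default_config)
        re = synthesize_capture(default_config, clean_scene, truth)
        cx = synthesize_capture(iq_config, clean_scene, truth)
        np.testing.assert_allclose(re.samples, cx.samples.real, atol=1e-12)


class TestReferenceMonitor:
    def _truth(self, config, apnea=()):
        profile = MotionProfile(
            duration=120.0, respiration_rate=85.0, apnea_intervals=apnea
        )
        return generate_displacement(profile, config)

    def test_constant_rate_reproduced_after_warmup(self, default_config):
        ref = emulate_reference_monitor(self._truth(default_config))
        settled = ref.rate[ref.timestamps > 35.0]
        np.testing.assert_allclose(settled, 85.0, atol=0.1)

    def test_short_apnea_only_partially_dips(self, default_config):
        truth = self._truth(default_config, apnea=[(50.0, 64.0)])
        ref = emulate_reference_monitor(truth, smoothing_window=30.0)
        assert ref.rate.min() > 0.0
        # window-average arithmetic: a 14 s pause in a 30 s window
        assert ref.rate.min() > (1.0 - 14.0 / 30.0) * 85.0 - 1.0

    def test_zero_window_limit_reproduces_truth(self, default_config):
        truth = self._truth(default_config, apnea=[(50.0, 64.0)])
        ref = emulate_reference_monitor(truth, smoothing_window=1e-6, output_rate=32.0)
        expected = np.where(
            np.isfinite(truth.true_rate.rate), truth.true_rate.rate, 0.0
        )
        got = np.interp(truth.timestamps, ref.timestamps, ref.rate)
        np.testing.assert_allclose(got, expected, atol=0.2)

    def test_invalid_window_rejected(self, default_config):
        with pytest.raises(ValueError, match="smoothing_window"):
            emulate_reference_monitor(self._truth(default_config), smoothing_window=0.0)
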