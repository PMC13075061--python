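import numpy as np
import pytest

from fmcwvitals import RadarConfig, RangeSpectrum, RawCapture, SlowTimeSeries, derive_params
from fmcwvitals.dsp import (
    combine_channels,
    detect_target_bin,
    detrend_ramps,
    extract_phase,
    split_ramps,
    to_range_domain,
)
from conftest import make_breathing_capture


def tone_capture(config, freqs_and_amps, n_ramps=4):
    """Real capture whose every ramp is a sum of fast-time cosines."""
    n = config.samples_per_ramp
    t = np.arange(n) / config.sampling_frequency
    ramp = sum(a * np.cos(2 * np.pi * f * t) for f, a in freqs_and_amps)
    samples = np.broadcast_to(
        ramp, (n_ramps, config.n_channels, n)
    ).copy()
    return RawCapture(samples, config)


class TestSplitRamps:
    def test_exact_multiple(self, default_config):
        stream = np.zeros((4, 320 * 128))
        cap = split_ramps(stream, default_config)
        assert cap.n_ramps == 320
        assert cap.samples.shape == (320, 4, 128)

    def test_partial_ramp_dropped_with_warning(self, default_config, caplog):
        stream = np.zeros((4, 320 * 128 + 50))
        with caplog.at_level("WARNING"):
            cap = split_ramps(stream, default_config)
        assert cap.n_ramps == 320
        assert any("partial ramp" in rec.message for rec in caplog.records)

    def test_no_complete_ramp_is_error(self, default_config):
        with pytest.raises(ValueError, match="no complete ramp"):
            split_ramps(np.zeros((4, 100)), default_config)

    def test_sample_order_preserved(self, default_config):
        stream = np.arange(4 * 2 * 128, dtype=float).reshape(4, 2 * 128)
        cap = split_ramps(stream, default_config)
        np.testing.assert_array_equal(cap.samples[0, 0], stream[0, :128])
        np.testing.assert_array_equal(cap.samples[1, 2], stream[2, 128:])

    def test_capture_passthrough(self, default_config):
        cap = RawCapture(np.zeros((2, 4, 128)), default_config)
        assert split_ramps(cap) is cap


class TestDetrendRamps:
    def test_exact_line_removed(self, default_config):
        n = np.arange(128, dtype=float)
        samples = np.broadcast_to(3.0 + 0.1 * n, (2, 4, 128)).copy()
        out = detrend_ramps(RawCapture(samples, default_config))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_constant_removed(self, default_config):
        out = detrend_ramps(RawCapture(np.full((2, 4, 128), 7.5), default_config))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_residual_has_no_linear_component(self, default_config):
        """Least-squares oracle: refitting the residual gives ~zero slope."""
        cap = tone_capture(default_config, [(64.0, 1.0)])
        cap.samples += 3.0 + 0.1 * np.arange(128)
        out = detrend_ramps(cap)
        n = np.arange(128, dtype=float)
        slope, intercept = np.polyfit(n, out.samples[0, 0], 1)
        assert abs(slope) < 1e-10 and abs(intercept) < 1e-10

    def test_idempotent(self, default_config):
        rng = np.random.default_rng(0)
        cap = RawCapture(rng.standard_normal((3, 4, 128)), default_config)
        once = detrend_ramps(cap)
        twice = detrend_ramps(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)


class TestToRangeDomain:
    def test_pure_tone_maps_to_expected_range(self, default_config):
        # 64 Hz beat = one un-padded bin = the 0.6 m range resolution
        cap = tone_capture(default_config, [(64.0, 1.0)])
        spec = to_range_domain(cap, window="boxcar", zero_pad_factor=1)
        mag = np.abs(spec.values[0, 0])
        assert np.argmax(mag) == 1
        assert spec.bin_ranges[1] == pytest.approx(
            derive_params(default_config).range_resolution
        )

    def test_two_tones_two_bins(self, default_config):
        cap = tone_capture(default_config, [(64.0, 1.0), (192.0, 0.8)])
        spec = to_range_domain(cap, window="boxcar", zero_pad_factor=1)
        mag = np.abs(spec.values[0, 0])
        peaks = np.argsort(mag)[-2:]
        assert set(peaks) == {1, 3}

    def test_zero_in_zero_out(self, default_config):
        cap = RawCapture(np.zeros((2, 4, 128)), default_config)
        spec = to_range_domain(cap)
        np.testing.assert_array_equal(spec.values, 0.0)

    def test_linearity(self, default_config):
        rng = np.random.default_rng(1)
        a = RawCapture(rng.standard_normal((2, 4, 128)), default_config)
        b = RawCapture(rng.standard_normal((2, 4, 128)), default_config)
        ab = RawCapture(a.samples + b.samples, default_config)
        lhs = to_range_domain(ab).values
        rhs = to_range_domain(a).values + to_range_domain(b).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_padded_bin_spacing(self, default_config):
        cap = tone_capture(default_config, [(64.0, 1.0)])
        spec = to_range_domain(cap, zero_pad_factor=4)
        dr = derive_params(default_config).range_bin_width
        assert np.diff(spec.bin_ranges)[0] == pytest.approx(dr / 4)

    def test_unknown_window_lists_supported(self, default_config):
        cap = tone_capture(default_config, [(64.0, 1.0)])
        with pytest.raises(ValueError, match="hann"):
            to_range_domain(cap, window="kaiser17")


def spectrum_from_magnitudes(config, mags, ramp_phases=None):
    """Synthetic RangeSpectrum with given per-bin magnitudes."""
    n_bins = len(mags)
    bin_width = derive_params(config).range_bin_width / 4
    values = np.tile(np.asarray(mags, dtype=complex), (8, config.n_channels, 1))
    if ramp_phases is not None:
        values = values * np.exp(1j * np.asarray(ramp_phases))[:, None, None]
    return RangeSpectrum(
        values=values,
        bin_ranges=np.arange(n_bins) * bin_width,
        window_name="hann",
        zero_pad_factor=4,
        config=config,
    )


class TestDetectTargetBin:
    def test_single_in_roi_peak(self, default_config):
        mags = np.full(12, 0.1)
        mags[3] = 5.0
        b, r = detect_target_bin(spectrum_from_magnitudes(default_config, mags))
        assert b == 3

    def test_out_of_roi_peak_ignored(self, default_config):
        mags = np.full(12, 0.1)
        mags[3] = 5.0
        mags[11] = 50.0  # 1.65 m, outside the 0.2-1.2 m gate
        b, _ = detect_target_bin(spectrum_from_magnitudes(default_config, mags))
        assert b == 3

    def test_flat_noise_raises_no_target(self, default_config):
        mags = np.full(12, 1.0)
        with pytest.raises(ValueError, match="no target"):
            detect_target_bin(spectrum_from_magnitudes(default_config, mags))

    def test_scaling_invariance(self, default_config):
        rng = np.random.default_rng(2)
        mags = rng.uniform(0.5, 1.0, 12)
        mags[5] = 30.0
        b1, _ = detect_target_bin(spectrum_from_magnitudes(default_config, mags))
        b2, _ = detect_target_bin(spectrum_from_magnitudes(default_config, mags * 137.0))
        assert b1 == b2 == 5


class TestExtractPhase:
    def test_static_target_constant_phase(self, iq_config, clean_scene):
        truth, capture = make_breathing_capture(
            iq_config, duration=5.0, amplitude_mm=0.0, scene=clean_scene
        )
        spec = to_range_domain(detrend_ramps(capture))
        b, _ = detect_target_bin(spec)
        slow = extract_phase(spec, b)
        spread = np.ptp(slow.phase_per_channel, axis=1)
        assert np.all(spread < 1e-6)

    @pytest.mark.parametrize("amp_mm", [1.0, 5.0])
    def test_phase_amplitude_matches_4pi_d_over_lambda(
        self, iq_config, clean_scene, amp_mm
    ):
        truth, capture = make_breathing_capture(
            iq_config, duration=30.0, amplitude_mm=amp_mm, scene=clean_scene
        )
        spec = to_range_domain(detrend_ramps(capture))
        b, _ = detect_target_bin(spec)
        slow = extract_phase(spec, b)
        lam = derive_params(iq_config).wavelength
        expected = 4.0 * np.pi * amp_mm * 1e-3 / lam
        for q in range(slow.n_channels):
            trace = slow.phase_per_channel[q]
            measured = np.ptp(trace) / 2.0
            assert measured == pytest.approx(expected, rel=0.01)
            # unwrapping leaves no 2 pi discontinuities
            assert np.max(np.abs(np.diff(trace))) < np.pi

    def test_invalid_bin_rejected(self, default_config):
        spec = spectrum_from_magnitudes(default_config, np.ones(12))
        with pytest.raises(ValueError, match="target_bin"):
            extract_phase(spec, 99)


class TestCombineChannels:
    def _series(self, traces):
        traces = np.asarray(traces, dtype=float)
        t = (np.arange(traces.shape[1]) + 0.5) / 32.0
        return SlowTimeSeries(
            timestamps=t, phase_per_channel=traces, target_bin=3, target_range=0.45
        )

    def test_identical_traces_preserved(self):
        t = np.arange(64) / 32.0
        trace = np.sin(2 * np.pi * 1.4 * t)
        combined = combine_channels(self._series([trace] * 4))
        np.testing.assert_allclose(
            combined.combined_phase, trace - trace.mean(), atol=1e-12
        )

    def test_sign_flip_corrected(self):
        t = np.arange(64) / 32.0
        trace = np.sin(2 * np.pi * 1.4 * t)
        combined = combine_channels(self._series([trace, -trace, trace, trace]))
        np.testing.assert_allclose(
            combined.combined_phase, trace - trace.mean(), atol=1e-12
        )

    def test_single_channel(self):
        trace = np.linspace(0.0, 3.0, 64)
        combined = combine_channels(self._series([trace]))
        np.testing.assert_allclose(
            combined.combined_phase, trace - trace.mean(), atol=1e-12
        )


class TestEndToEnd:
    def test_noiseless_chain_recovers_displacement(self, iq_config, clean_scene):
        """x_hat = lambda * phase / (4 pi) matches the injected motion."""
        truth, capture = make_breathing_capture(
            iq_config, duration=30.0, amplitude_mm=1.5, scene=clean_scene
        )
        spec = to_range_domain(detrend_ramps(capture))
        b, _ = detect_target_bin(spec)
        slow = combine_channels(extract_phase(spec, b))
        lam = derive_params(iq_config).wavelength
        x_hat = lam * slow.combined_phase / (4.0 * np.pi)
        x_true = truth.displacement_m - truth.displacement_m.mean()
        rel_rms = np.sqrt(np.mean((x_hat - x_true) ** 2) / np.mean(x_true**2))
        assert rel_rms < 0.02
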