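"""Raw capture to combined slow-time phase: the range-gated demodulation chain.

Stage order: channel/ramp splitting -> per-ramp linear detrending (static
close-range clutter suppression) -> windowed range transform -> target
detection inside a range of interest -> per-channel phase extraction and
unwrapping -> sign-aligned channel combination.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import get_window

from .core import (
    AcquisitionMode,
    RadarConfig,
    RangeSpectrum,
    RawCapture,
    SlowTimeSeries,
    derive_params,
)

__all__ = [
    "split_ramps",
    "detrend_ramps",
    "to_range_domain",
    "detect_target_bin",
    "extract_phase",
    "combine_channels",
    "SUPPORTED_WINDOWS",
]

logger = logging.getLogger(__name__)

SUPPORTED_WINDOWS = ("boxcar", "hann", "hamming", "blackman", "blackmanharris", "flattop")


def split_ramps(
    samples: np.ndarray | RawCapture,
    config: RadarConfig | None = None,
    start_time: float = 0.0,
) -> RawCapture:
    """Assign a contiguous per-channel sample stream to ramps.

    *samples* may be a flat array of shape ``(n_channels, n_total)`` (or
    ``(n_total,)`` for a single channel), or an already ramp-indexed
    :class:`RawCapture`, which is returned unchanged.  A trailing partial
    ramp is dropped with a warning; a stream with no complete ramp is an
    error.
    """
    if isinstance(samples, RawCapture):
        return samples
    if config is None:
        raise ValueError("config is required when splitting a raw sample stream")
    arr = np.asarray(samples)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected a (n_channels, n_samples) stream, got shape {arr.shape}")
    if arr.shape[0] != config.n_channels:
        raise ValueError(
            f"stream has {arr.shape[0]} channels, config expects {config.n_channels}"
        )
    n = config.samples_per_ramp
    n_ramps, remainder = divmod(arr.shape[1], n)
    if n_ramps == 0:
        raise ValueError("no complete ramp in capture")
    if remainder:
        logger.warning(
            "dropping trailing partial ramp of %d samples (%d complete ramps kept)",
            remainder,
            n_ramps,
        )
        arr = arr[:, : n_ramps * n]
    ramped = arr.reshape(config.n_channels, n_ramps, n).transpose(1, 0, 2).copy()
    return RawCapture(samples=ramped, config=config, start_time=start_time, n_ramps=n_ramps)


def detrend_ramps(capture: RawCapture) -> RawCapture:
    """Subtract the least-squares line over fast time from every ramp.

    DC and linear fast-time components alias into the lowest beat
    frequencies, i.e. into apparent close-range returns; removing them per
    ramp and channel suppresses that static leakage.  Idempotent: the
    residual has zero mean and zero linear trend.
    """
    y = capture.samples
    n = y.shape[-1]
    if n < 2:
        raise ValueError("detrend_ramps requires at least 2 samples per ramp")
    x = np.arange(n, dtype=float)
    x_centered = x - x.mean()
    denom = np.dot(x_centered, x_centered)
    mean = y.mean(axis=-1, keepdims=True)
    slope = np.tensordot(y - mean, x_centered, axes=([-1], [0]))[..., None] / denom
    residual = y - mean - slope * x_centered
    return RawCapture(
        samples=residual,
        config=capture.config,
        start_time=capture.start_time,
        n_ramps=capture.n_ramps,
    )


def to_range_domain(
    capture: RawCapture,
    window: str = "hann",
    zero_pad_factor: int = 4,
) -> RangeSpectrum:
    """Windowed, zero-padded fast-time DFT of every ramp.

    Only the non-negative-range half spectrum is kept.  Bin ``b`` maps to
    range ``b * c / (2 B zero_pad_factor)``, so the un-padded bin width
    equals the range resolution.  Zero padding interpolates the peak of a
    target lying between coarse bins (with the defaults the standoff of
    0.4 m falls below one un-padded 0.6 m bin).
    """
    if zero_pad_factor < 1:
        raise ValueError(f"zero_pad_factor must be >= 1, got {zero_pad_factor}")
    if window not in SUPPORTED_WINDOWS:
        raise ValueError(
            f"unknown window {window!r}; supported windows: {', '.join(SUPPORTED_WINDOWS)}"
        )
    n = capture.config.samples_per_ramp
    w = get_window(window, n, fftbins=True)
    n_pad = n * zero_pad_factor
    spectrum = np.fft.fft(capture.samples * w, n=n_pad, axis=-1)
    n_keep = n_pad // 2 + 1
    spectrum = spectrum[..., :n_keep]
    bin_width = derive_params(capture.config).range_bin_width / zero_pad_factor
    bin_ranges = np.arange(n_keep) * bin_width
    return RangeSpectrum(
        values=spectrum,
        bin_ranges=bin_ranges,
        window_name=window,
        zero_pad_factor=zero_pad_factor,
        config=capture.config,
        start_time=capture.start_time,
    )


def detect_target_bin(
    spectrum: RangeSpectrum,
    roi: tuple[float, float] = (0.2, 1.2),
    noise_floor_multiple: float = 3.0,
) -> tuple[int, float]:
    """Pick the breathing-target range bin inside the range of interest.

    Returns the argmax of the ramp- and channel-averaged magnitude
    restricted to *roi* (ties break to the lower bin).  If that maximum does
    not exceed *noise_floor_multiple* times the median magnitude over all
    bins, no plausible target exists and an error is raised.  Invariant to
    global amplitude scaling.
    """
    lo, hi = roi
    mask = (spectrum.bin_ranges >= lo) & (spectrum.bin_ranges <= hi)
    if not mask.any():
        raise ValueError(
            f"roi ({lo}, {hi}) m contains no range bin "
            f"(bins span 0 to {spectrum.bin_ranges[-1]:.2f} m)"
        )
    mag = np.abs(spectrum.values).mean(axis=(0, 1))
    floor = np.median(mag)
    roi_indices = np.flatnonzero(mask)
    best = roi_indices[int(np.argmax(mag[roi_indices]))]
    if mag[best] < noise_floor_multiple * floor:
        raise ValueError(
            "no target: range-of-interest maximum "
            f"({mag[best]:.3g}) below {noise_floor_multiple} x median magnitude ({floor:.3g})"
        )
    target_range = float(spectrum.bin_ranges[best])
    logger.info("target detected at bin %d (%.3f m)", best, target_range)
    return int(best), target_range


def extract_phase(spectrum: RangeSpectrum, target_bin: int) -> SlowTimeSeries:
    """Unwrapped slow-time phase at *target_bin*, one trace per channel.

    Unwrapping uses the conventional pi jump threshold, valid because the
    maximum unambiguous speed bounds the per-ramp phase step upstream.  For
    I-only captures the spectrum is already the positive-frequency half of
    a real signal, which retains the target phase.
    """
    if not (0 <= target_bin < spectrum.values.shape[2]):
        raise ValueError(f"target_bin {target_bin} outside spectrum with "
                         f"{spectrum.values.shape[2]} bins")
    raw_phase = np.angle(spectrum.values[:, :, target_bin])  # (ramp, channel)
    unwrapped = np.unwrap(raw_phase, axis=0).T  # (channel, ramp)
    n_ramps = spectrum.values.shape[0]
    timestamps = spectrum.start_time + (np.arange(n_ramps) + 0.5) / spectrum.config.ramp_rate
    return SlowTimeSeries(
        timestamps=timestamps,
        phase_per_channel=unwrapped,
        target_bin=int(target_bin),
        target_range=float(spectrum.bin_ranges[target_bin]),
    )


def combine_channels(series: SlowTimeSeries) -> SlowTimeSeries:
    """Average the per-channel phase traces into one breathing-motion trace.

    Each trace is mean-centered and sign-aligned to channel 0 by the sign
    of its correlation with channel 0, then averaged with equal weights.
    Sign alignment protects against a channel whose geometry inverts the
    apparent motion; equal weighting is the simplest deterministic rule.
    """
    phases = series.phase_per_channel
    centered = phases - phases.mean(axis=1, keepdims=True)
    signs = np.ones(centered.shape[0])
    for q in range(1, centered.shape[0]):
        c = float(np.dot(centered[q], centered[0]))
        signs[q] = -1.0 if c < 0 else 1.0
    combined = (signs[:, None] * centered).mean(axis=0)
    return SlowTimeSeries(
        timestamps=series.timestamps,
        phase_per_channel=series.phase_per_channel,
        target_bin=series.target_bin,
        target_range=series.target_range,
        combined_phase=combined,
    )
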