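"""End-to-end orchestration: capture -> rate series + apnea events."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import dsp, vitals
from .config import PipelineConfig
from .core import ApneaEvent, RateSeries, RawCapture, SlowTimeSeries

__all__ = ["ProcessingResult", "process_capture"]

logger = logging.getLogger(__name__)


@dataclass
class ProcessingResult:
    """Everything the processing chain produced for one capture."""

    slow_time: SlowTimeSeries
    filtered: SlowTimeSeries
    breath_times: np.ndarray
    rates: RateSeries
    apnea_events: list[ApneaEvent]
    target_bin: int
    target_range: float


def process_capture(
    capture: RawCapture, config: PipelineConfig | None = None
) -> ProcessingResult:
    """Run the full chain: detrend -> range transform -> target detection ->
    phase extraction -> channel combination -> respiration filter -> breath
    peaks -> sliding-window rate -> apnea events."""
    cfg = config or PipelineConfig(radar=capture.config)
    logger.info("processing capture: %d ramps, %d channels", capture.n_ramps,
                capture.config.n_channels)
    detrended = dsp.detrend_ramps(capture)
    spectrum = dsp.to_range_domain(
        detrended, window=cfg.dsp.window, zero_pad_factor=cfg.dsp.zero_pad_factor
    )
    target_bin, target_range = dsp.detect_target_bin(
        spectrum, roi=cfg.dsp.roi, noise_floor_multiple=cfg.dsp.noise_floor_multiple
    )
    per_channel = dsp.extract_phase(spectrum, target_bin)
    combined = dsp.combine_channels(per_channel)
    filtered = vitals.filter_respiration(combined, band=cfg.vitals.band)
    breath_times = vitals.detect_breaths(filtered, prominence=cfg.vitals.prominence)
    duration = capture.n_ramps / capture.config.ramp_rate
    rates = vitals.rate_series(
        breath_times,
        window=cfg.vitals.rate_window,
        step=cfg.vitals.rate_step,
        duration=duration,
        start_time=capture.start_time,
        band=cfg.vitals.rate_band,
    )
    events = vitals.detect_apnea(
        filtered,
        breath_times,
        min_duration=cfg.vitals.apnea_min_duration,
        rms_fraction=cfg.vitals.apnea_rms_fraction,
        rms_window=cfg.vitals.rms_window,
    )
    logger.info(
        "capture processed: target bin %d (%.2f m), %d peaks, %d apnea event(s)",
        target_bin, target_range, breath_times.size, len(events),
    )
    return ProcessingResult(
        slow_time=combined,
        filtered=filtered,
        breath_times=breath_times,
        rates=rates,
        apnea_events=events,
        target_bin=target_bin,
        target_range=target_range,
    )
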