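"""Shared domain types for FMCW radar respiration monitoring.

The pipeline works with a de-chirped (beat-signal) representation of a
frequency-modulated continuous-wave radar.  One *ramp* is a linear frequency
sweep sampled in *fast time*; the sequence of ramps forms the *slow-time*
axis, sampled at the ramp repetition rate.  A scatterer at range ``R``
produces a beat tone at ``f_b = 2 R B / (c T_ramp)`` whose phase advances by
``4 pi R / lambda`` — sub-millimeter chest motion is therefore visible as a
slow-time phase modulation even though the range resolution ``c / (2 B)`` is
on the order of half a meter.

All types validate their invariants at construction time and raise
:class:`ValueError` naming the offending field.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT",
    "RATE_SENTINEL",
    "AcquisitionMode",
    "RateSource",
    "RadarConfig",
    "DerivedParams",
    "derive_params",
    "RawCapture",
    "RangeSpectrum",
    "SlowTimeSeries",
    "RateSeries",
    "ApneaEvent",
    "AgreementReport",
]

SPEED_OF_LIGHT = 299_792_458.0
"""Speed of light in vacuum, m/s."""

RATE_SENTINEL = float("nan")
"""Explicit "rate undeterminable" marker (NaN).

Never conflated with 0 bpm: zero breathing is a physiologically meaningful
apnea value, whereas the sentinel means the estimator had too little
evidence (e.g. fewer than two breath peaks in the analysis window).
"""


class AcquisitionMode(str, enum.Enum):
    """Which baseband components the receiver digitizes.

    ``I_ONLY`` keeps only the in-phase (real) component of the de-chirped
    signal; ``IQ`` keeps the full complex baseband.  Processing with I-only
    data is possible because the positive-frequency half spectrum of a real
    signal retains the target phase, at the cost of conjugate-image leakage.
    """

    I_ONLY = "i_only"
    IQ = "iq"


class RateSource(str, enum.Enum):
    """Provenance of a breathing-rate series."""

    RADAR = "radar"
    REFERENCE = "reference"
    GROUND_TRUTH = "ground_truth"


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class RadarConfig:
    """Static parameters of the FMCW front end.

    Defaults describe a 24 GHz ISM-band sensor with 250 MHz sweep bandwidth,
    128 fast-time samples per ramp at 8192 Hz, a 32 Hz ramp repetition rate
    and four receive channels, mounted ~0.4 m above the subject.

    ``wavelength_override`` replaces the carrier-derived wavelength in all
    derived quantities.  The physical wavelength at 24.125 GHz is ~12.4 mm;
    the override exists to reproduce datasheet-style round numbers (e.g. a
    12.5 cm wavelength giving a 1 m/s maximum unambiguous speed) without
    changing the default physics.
    """

    carrier_frequency: float = 24.125e9
    bandwidth: float = 250e6
    samples_per_ramp: int = 128
    sampling_frequency: float = 8192.0
    ramp_rate: float = 32.0
    n_channels: int = 4
    acquisition_mode: AcquisitionMode = AcquisitionMode.I_ONLY
    standoff: float = 0.4
    wavelength_override: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "carrier_frequency",
            "bandwidth",
            "sampling_frequency",
            "ramp_rate",
            "standoff",
        ):
            _require_positive(name, getattr(self, name))
        if int(self.samples_per_ramp) != self.samples_per_ramp or self.samples_per_ramp < 1:
            raise ValueError(
                f"samples_per_ramp must be a positive integer, got {self.samples_per_ramp!r}"
            )
        if int(self.n_channels) != self.n_channels or self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels!r}")
        if self.wavelength_override is not None:
            _require_positive("wavelength_override", self.wavelength_override)
        mode = AcquisitionMode(self.acquisition_mode)
        object.__setattr__(self, "acquisition_mode", mode)
        # the ramp must fit inside its repetition period
        ramp_duration = self.samples_per_ramp / self.sampling_frequency
        if ramp_duration > 1.0 / self.ramp_rate + 1e-12:
            raise ValueError(
                "samples_per_ramp / sampling_frequency "
                f"({ramp_duration:g} s) exceeds the ramp repetition period "
                f"1 / ramp_rate ({1.0 / self.ramp_rate:g} s)"
            )

    @property
    def wavelength(self) -> float:
        """Carrier wavelength in meters (override-aware)."""
        if self.wavelength_override is not None:
            return self.wavelength_override
        return SPEED_OF_LIGHT / self.carrier_frequency

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["acquisition_mode"] = self.acquisition_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RadarConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class DerivedParams:
    """Quantities derived from a :class:`RadarConfig`.

    - ``range_resolution``: c / (2 B) — also the un-padded range-bin width.
    - ``ramp_duration``: fast-time span of one ramp.
    - ``max_unambiguous_speed``: lambda * ramp_rate / 4, the fastest radial
      target speed whose per-ramp phase step stays below pi.
    - ``slow_time_rate``: the sampling rate of the phase trace (= ramp rate).
    """

    wavelength: float
    range_resolution: float
    ramp_duration: float
    range_bin_width: float
    max_unambiguous_speed: float
    slow_time_rate: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require_positive(f.name, getattr(self, f.name))


def derive_params(config: RadarConfig) -> DerivedParams:
    """Compute the derived radar quantities for *config*.

    Deterministic and scale-covariant: doubling the bandwidth exactly halves
    the range resolution.  Uses the carrier-derived wavelength unless
    ``config.wavelength_override`` is set.
    """
    wavelength = config.wavelength
    range_resolution = SPEED_OF_LIGHT / (2.0 * config.bandwidth)
    ramp_duration = config.samples_per_ramp / config.sampling_frequency
    return DerivedParams(
        wavelength=wavelength,
        range_resolution=range_resolution,
        ramp_duration=ramp_duration,
        range_bin_width=range_resolution,
        max_unambiguous_speed=wavelength * config.ramp_rate / 4.0,
        slow_time_rate=config.ramp_rate,
    )


@dataclass
class RawCapture:
    """De-chirped baseband samples, indexed ``[ramp, channel, fast_time]``.

    Real-valued in ``i_only`` mode, complex-valued in ``iq`` mode.
    """

    samples: np.ndarray
    config: RadarConfig
    start_time: float = 0.0
    n_ramps: int = field(default=-1)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 3:
            raise ValueError(
                f"samples must be 3-axis [ramp, channel, fast_time], got shape {self.samples.shape}"
            )
        if self.n_ramps == -1:
            self.n_ramps = self.samples.shape[0]
        m, q, n = self.samples.shape
        if m != self.n_ramps:
            raise ValueError(f"n_ramps ({self.n_ramps}) does not match samples axis 0 ({m})")
        if q != self.config.n_channels:
            raise ValueError(
                f"samples channel axis ({q}) does not match config.n_channels ({self.config.n_channels})"
            )
        if n != self.config.samples_per_ramp:
            raise ValueError(
                f"samples fast-time axis ({n}) does not match config.samples_per_ramp "
                f"({self.config.samples_per_ramp})"
            )
        complex_data = np.iscomplexobj(self.samples)
        if self.config.acquisition_mode is AcquisitionMode.IQ and not complex_data:
            raise ValueError("iq acquisition_mode requires complex samples")
        if self.config.acquisition_mode is AcquisitionMode.I_ONLY and complex_data:
            raise ValueError("i_only acquisition_mode requires real samples")
        if not np.all(np.isfinite(self.samples if not complex_data else self.samples.view(float))):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Capture length in seconds of slow time."""
        return self.n_ramps / self.config.ramp_rate


@dataclass
class RangeSpectrum:
    """Per-ramp, per-channel range-domain transform of a capture.

    ``bin_ranges[b]`` is the range (m) mapped to bin ``b``; with zero padding
    the bin spacing is ``range_bin_width / zero_pad_factor``.  Only the
    non-negative-range half spectrum is kept.
    """

    values: np.ndarray
    bin_ranges: np.ndarray
    window_name: str
    zero_pad_factor: int
    config: RadarConfig
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.bin_ranges = np.asarray(self.bin_ranges, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-axis, got shape {self.values.shape}")
        if self.values.shape[2] != self.bin_ranges.size:
            raise ValueError("bin_ranges length does not match values range axis")
        if self.bin_ranges[0] != 0 or np.any(np.diff(self.bin_ranges) <= 0):
            raise ValueError("bin_ranges must increase monotonically from 0")
        if self.zero_pad_factor < 1:
            raise ValueError(f"zero_pad_factor must be >= 1, got {self.zero_pad_factor}")

    @property
    def n_ramps(self) -> int:
        return self.values.shape[0]


@dataclass
class SlowTimeSeries:
    """Unwrapped target-bin phase versus slow time.

    ``phase_per_channel`` has one unwrapped trace per receive channel;
    ``combined_phase`` is filled in by channel combination (``None`` before).
    Timestamps are uniform at the ramp rate, taken at ramp centers.
    """

    timestamps: np.ndarray
    phase_per_channel: np.ndarray
    target_bin: int
    target_range: float
    combined_phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.phase_per_channel = np.atleast_2d(np.asarray(self.phase_per_channel, dtype=float))
        if self.phase_per_channel.shape[1] != self.timestamps.size:
            raise ValueError("phase_per_channel length does not match timestamps")
        dt = np.diff(self.timestamps)
        if self.timestamps.size > 1:
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("timestamps must be uniformly spaced")
        jump_limit = np.pi * (1.0 + 1e-9)
        if self.timestamps.size > 1 and np.any(
            np.abs(np.diff(self.phase_per_channel, axis=1)) > jump_limit
        ):
            raise ValueError(
                "phase_per_channel contains a jump exceeding pi between consecutive samples; "
                "traces must be unwrapped"
            )
        if self.combined_phase is not None:
            self.combined_phase = np.asarray(self.combined_phase, dtype=float)
            if self.combined_phase.shape != self.timestamps.shape:
                raise ValueError("combined_phase length does not match timestamps")

    @property
    def sample_rate(self) -> float:
        if self.timestamps.size < 2:
            raise ValueError("sample_rate undefined for fewer than 2 samples")
        return 1.0 / (self.timestamps[1] - self.timestamps[0])

    @property
    def n_channels(self) -> int:
        return self.phase_per_channel.shape[0]


#: default physiological plausibility band for breathing rates, bpm
DEFAULT_RATE_BAND = (6.0, 180.0)


@dataclass
class RateSeries:
    """Timestamped breathing-rate estimates in breaths per minute.

    Entries are either within the physiological band or the NaN sentinel
    (rate undeterminable); see :data:`RATE_SENTINEL`.
    """

    timestamps: np.ndarray
    rate: np.ndarray
    source: RateSource
    band: tuple[float, float] = DEFAULT_RATE_BAND

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.source = RateSource(self.source)
        if self.timestamps.shape != self.rate.shape:
            raise ValueError("timestamps and rate must have the same length")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        lo, hi = self.band
        finite = np.isfinite(self.rate)
        if np.any((self.rate[finite] < lo) | (self.rate[finite] > hi)):
            raise ValueError(
                f"rates must be within the physiological band [{lo}, {hi}] bpm or the sentinel"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-sentinel entries."""
        return np.isfinite(self.rate)


@dataclass(frozen=True)
class ApneaEvent:
    """A detected respiratory pause, in seconds from capture start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"end ({self.end}) must be after start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


def validate_event_list(events: list[ApneaEvent], min_duration: float = 0.0) -> None:
    """Check that *events* are sorted, disjoint and each at least *min_duration*."""
    for i, ev in enumerate(events):
        if ev.duration < min_duration:
            raise ValueError(f"event {i} shorter than min_duration {min_duration}")
        if i and ev.start < events[i - 1].end:
            raise ValueError(f"events {i - 1} and {i} overlap or are unsorted")


@dataclass
class AgreementReport:
    """Method-comparison summary between radar and reference rate series.

    ``lag`` is the time shift (s) applied to the radar series to align it
    with the reference.  ``mean_difference`` and the limits of agreement
    (``loa_lower``/``loa_upper`` = bias -/+ 1.96 SD) are in bpm, oriented
    radar minus reference.  ``relative_differences`` are percentages paired
    with per-sample mean rates (``mean_rates``, bpm).
    """

    lag: float
    r_squared: float
    mean_difference: float
    loa_lower: float
    loa_upper: float
    relative_differences: np.ndarray
    mean_rates: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.relative_differences = np.asarray(self.relative_differences, dtype=float)
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        if not (self.loa_lower - 1e-12 <= self.mean_difference <= self.loa_upper + 1e-12):
            raise ValueError("limits of agreement must bracket the mean difference")
        if self.relative_differences.shape != self.mean_rates.shape:
            raise ValueError("relative_differences and mean_rates must have the same length")

    def to_dict(self) -> dict:
        return {
            "lag_s": float(self.lag),
            "r_squared": float(self.r_squared),
            "mean_difference_bpm": float(self.mean_difference),
            "loa_lower_bpm": float(self.loa_lower),
            "loa_upper_bpm": float(self.loa_upper),
            "n_pairs": int(self.n_pairs),
            "mean_rates_bpm": [float(x) for x in self.mean_rates],
            "relative_differences_pct": [float(x) for x in self.relative_differences],
        }
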