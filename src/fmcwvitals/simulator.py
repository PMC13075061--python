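"""Synthetic breathing scenes and de-chirped FMCW baseband synthesis.

This module stands in for recordings of sedated newborn piglets in an
incubator: thoracic displacements of 0.5–3 mm at 60–100 breaths/min with a
superimposed cardiac micro-motion, the sensor ~0.4 m above the animal,
occasional apneas and gross-motion episodes, plus static clutter from
incubator structures.  It produces

* a slow-time ground-truth displacement trace (:func:`generate_displacement`),
* the multi-channel de-chirped baseband capture a real front end would
  digitize (:func:`synthesize_capture`), and
* an emulated cable-based reference monitor (:func:`emulate_reference_monitor`)
  whose wide averaging window makes it blind to short apneas.

The beat-signal model for a scatterer at range ``R`` with amplitude ``A``
seen by channel ``q`` (gain ``g_q``, phase offset ``psi_q``) is

    A * g_q * exp(j (2 pi f_b n / f_s + 4 pi R / lambda + psi_q)),

with beat frequency ``f_b = 2 R B / (c T_ramp)`` and fast-time sample index
``n``.  No RF-level chirp is synthesized — the processing chain consumes
baseband only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .core import (
    AcquisitionMode,
    RadarConfig,
    RateSeries,
    RateSource,
    RawCapture,
    RATE_SENTINEL,
    SPEED_OF_LIGHT,
)

__all__ = [
    "MotionProfile",
    "SceneConfig",
    "GroundTruth",
    "generate_displacement",
    "synthesize_capture",
    "emulate_reference_monitor",
]

RateFunction = Callable[[np.ndarray], np.ndarray]


def _check_intervals(intervals, duration: float, what: str) -> list[tuple]:
    out = sorted(tuple(iv) for iv in intervals)
    for iv in out:
        if iv[1] <= iv[0]:
            raise ValueError(f"{what} interval {iv} has non-positive length")
        if iv[0] < 0 or iv[1] > duration:
            raise ValueError(f"{what} interval {iv} outside [0, {duration}]")
    for a, b in zip(out, out[1:]):
        if b[0] < a[1]:
            raise ValueError(f"{what} intervals {a} and {b} overlap")
    return out


@dataclass
class MotionProfile:
    """Ground-truth thoracic motion description.

    ``respiration_rate`` is either a constant (bpm) or a callable mapping a
    time array (s) to bpm, allowing slowly drifting rates.  ``waveform``
    selects the breath shape: a pure sinusoid, or an asymmetric raised
    cosine whose inhale is faster than its exhale (closer to real
    pneumograms).  Amplitudes are millimeters of radial chest displacement.
    Gross-motion episodes are ``(start, end, amplitude_mm)`` triples
    rendered as band-limited random walks.
    """

    duration: float
    respiration_rate: float | RateFunction = 85.0
    respiration_amplitude_mm: float = 1.5
    waveform: str = "sinusoid"
    cardiac_rate: float = 200.0
    cardiac_amplitude_mm: float = 0.1
    apnea_intervals: Sequence[tuple[float, float]] = ()
    motion_intervals: Sequence[tuple[float, float, float]] = ()
    nominal_range_m: float = 0.4

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        for name in ("respiration_amplitude_mm", "cardiac_amplitude_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.waveform not in ("sinusoid", "asymmetric"):
            raise ValueError(f"waveform must be 'sinusoid' or 'asymmetric', got {self.waveform!r}")
        if not (6.0 <= self.cardiac_rate <= 300.0):
            raise ValueError(f"cardiac_rate must be within 6-300 bpm, got {self.cardiac_rate}")
        if not callable(self.respiration_rate):
            if not (6.0 <= self.respiration_rate <= 300.0):
                raise ValueError(
                    f"respiration_rate must be within 6-300 bpm, got {self.respiration_rate}"
                )
        self.apnea_intervals = _check_intervals(self.apnea_intervals, self.duration, "apnea")
        self.motion_intervals = _check_intervals(self.motion_intervals, self.duration, "motion")
        for iv in self.motion_intervals:
            if len(iv) != 3 or iv[2] < 0:
                raise ValueError(f"motion interval {iv} must be (start, end, amplitude_mm >= 0)")

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous configured breathing rate (bpm) at times *t*."""
        if callable(self.respiration_rate):
            r = np.asarray(self.respiration_rate(np.asarray(t, dtype=float)), dtype=float)
        else:
            r = np.full(np.shape(t), float(self.respiration_rate))
        if np.any(r < 6.0) or np.any(r > 300.0):
            raise ValueError("respiration_rate function left the 6-300 bpm band")
        return r


@dataclass
class SceneConfig:
    """Propagation-scene nuisances: clutter, noise and channel mismatch.

    ``clutter_targets`` are static scatterers as ``(range_m, amplitude)``
    relative to the unit-amplitude breathing target; the default single
    scatterer at 0.9 m with amplitude 0.5 mimics an incubator-lid
    reflection inside the range of interest.  ``noise_sigma`` is the
    additive white Gaussian noise standard deviation per real sample
    component, relative to unit target amplitude (0.3 ~ 10 dB per-sample
    SNR before any processing gain).
    """

    clutter_targets: Sequence[tuple[float, float]] = ((0.9, 0.5),)
    noise_sigma: float = 0.3
    channel_gains: Sequence[float] | None = None
    channel_phase_offsets: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for r, a in self.clutter_targets:
            if r < 0:
                raise ValueError(f"clutter range must be >= 0, got {r}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")

    def gains(self, n_channels: int) -> np.ndarray:
        g = np.ones(n_channels) if self.channel_gains is None else np.asarray(
            self.channel_gains, dtype=float
        )
        if g.size != n_channels:
            raise ValueError(f"channel_gains must have {n_channels} entries")
        return g

    def phase_offsets(self, n_channels: int) -> np.ndarray:
        p = np.zeros(n_channels) if self.channel_phase_offsets is None else np.asarray(
            self.channel_phase_offsets, dtype=float
        )
        if p.size != n_channels:
            raise ValueError(f"channel_phase_offsets must have {n_channels} entries")
        return p


@dataclass
class GroundTruth:
    """Slow-time truth the simulator hands to the synthesis and evaluation.

    ``displacement_m`` is the total chest position in meters,
    ``R0 + resp(t) + cardiac(t) + motion(t)``, sampled at the ramp rate;
    ``true_rate`` carries the configured breathing rate with the sentinel
    inside apnea intervals.
    """

    timestamps: np.ndarray
    displacement_m: np.ndarray
    true_rate: RateSeries
    apnea_intervals: Sequence[tuple[float, float]]
    profile: MotionProfile

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.displacement_m = np.asarray(self.displacement_m, dtype=float)
        if self.timestamps.shape != self.displacement_m.shape:
            raise ValueError("timestamps and displacement_m must have the same length")
        if not np.all(np.isfinite(self.displacement_m)):
            raise ValueError("displacement_m must be finite")


def _respiration_waveform(phase: np.ndarray, waveform: str) -> np.ndarray:
    """Unit-amplitude breath shape as a function of cycle phase (radians)."""
    if waveform == "sinusoid":
        return np.sin(phase)
    # asymmetric: raised-cosine inhale over 35% of the cycle, exhale over 65%
    u = np.mod(phase / (2.0 * np.pi), 1.0)
    inhale_frac = 0.35
    x = np.where(
        u < inhale_frac,
        0.5 * (1.0 - np.cos(np.pi * u / inhale_frac)),
        0.5 * (1.0 + np.cos(np.pi * (u - inhale_frac) / (1.0 - inhale_frac))),
    )
    return x - 0.5  # center around 0 like the sinusoid


def _gross_motion(
    t: np.ndarray, intervals, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian random-walk episodes, meters.

    Each episode is a Gaussian random walk band-limited to 0.15-4 Hz and
    scaled so its standard deviation equals the episode amplitude.  The
    band-pass keeps the walk's red-noise character while guaranteeing the
    episode carries energy at breathing-like frequencies: an unfiltered
    walk concentrates nearly all its power in sub-0.1 Hz drift, which gross
    body movement does not — limbs and head move with velocity content
    across the whole low-frequency band.
    """
    out = np.zeros_like(t)
    if not intervals:
        return out
    sos = sps.butter(2, (0.15, min(4.0, 0.45 * fs)), btype="bandpass", fs=fs, output="sos")
    for start, end, amp_mm in intervals:
        mask = (t >= start) & (t < end)
        n = int(mask.sum())
        if n < 8 or amp_mm == 0:
            continue
        walk = np.cumsum(rng.standard_normal(n))
        walk = sps.sosfiltfilt(sos, walk)
        walk -= walk.mean()
        std = walk.std()
        if std > 0:
            walk *= (amp_mm * 1e-3) / std
        # taper edges so the episode joins the resting position smoothly
        walk *= sps.windows.tukey(n, alpha=min(1.0, 16.0 / n))
        out[mask] = walk
    return out


def generate_displacement(
    profile: MotionProfile, config: RadarConfig, seed: int = 0
) -> GroundTruth:
    """Render the slow-time chest-position trace for *profile*.

    The respiration component has instantaneous frequency ``rate(t)/60`` and
    is gated to exactly zero inside apnea intervals (cardiac micro-motion
    and gross motion persist).  Identical ``(profile, config, seed)`` yield
    bit-identical traces.
    """
    fs = config.ramp_rate
    n = int(round(profile.duration * fs))
    if n < 1:
        raise ValueError("duration too short for one ramp")
    t = (np.arange(n) + 0.5) / fs  # ramp-center timestamps

    rate_bpm = profile.rate_at(t)
    inst_freq = rate_bpm / 60.0
    phase = 2.0 * np.pi * cumulative_trapezoid(inst_freq, t, initial=0.0)
    resp = profile.respiration_amplitude_mm * 1e-3 * _respiration_waveform(
        phase, profile.waveform
    )

    apnea_mask = np.zeros(n, dtype=bool)
    for start, end in profile.apnea_intervals:
        apnea_mask |= (t >= start) & (t < end)
    resp[apnea_mask] = 0.0

    cardiac = profile.cardiac_amplitude_mm * 1e-3 * np.sin(
        2.0 * np.pi * profile.cardiac_rate / 60.0 * t
    )
    rng = np.random.default_rng(seed)
    motion = _gross_motion(t, profile.motion_intervals, fs, rng)

    displacement = profile.nominal_range_m + resp + cardiac + motion

    true_rate = np.where(apnea_mask, RATE_SENTINEL, rate_bpm)
    rate_series = RateSeries(
        timestamps=t, rate=true_rate, source=RateSource.GROUND_TRUTH
    )
    return GroundTruth(
        timestamps=t,
        displacement_m=displacement,
        true_rate=rate_series,
        apnea_intervals=profile.apnea_intervals,
        profile=profile,
    )


def synthesize_capture(
    config: RadarConfig, scene: SceneConfig, truth: GroundTruth
) -> RawCapture:
    """Synthesize the de-chirped multi-channel baseband capture.

    Each scatterer contributes a fast-time beat tone whose frequency encodes
    its range and whose phase advances by ``4 pi R / lambda``; the breathing
    target follows ``truth.displacement_m`` ramp by ramp while clutter stays
    fixed.  In ``i_only`` mode the real part is stored.
    """
    n_ramps = truth.timestamps.size
    if n_ramps and not math.isclose(
        truth.timestamps[1] - truth.timestamps[0], 1.0 / config.ramp_rate, rel_tol=1e-9
    ):
        raise ValueError("truth must be sampled at config.ramp_rate")

    n = config.samples_per_ramp
    q = config.n_channels
    fs = config.sampling_frequency
    t_ramp = n / fs
    lam = config.wavelength
    # f_b = 2 R B / (c T_ramp)
    beat_coeff = 2.0 * config.bandwidth / (SPEED_OF_LIGHT * t_ramp)

    scatterers: list[tuple[np.ndarray, float]] = [(truth.displacement_m, 1.0)]
    for r_k, a_k in scene.clutter_targets:
        scatterers.append((np.full(n_ramps, float(r_k)), float(a_k)))

    max_range = max(float(np.max(r)) for r, _ in scatterers) if scatterers else 0.0
    if beat_coeff * max_range >= fs / 2.0:
        raise ValueError(
            f"target beat frequency {beat_coeff * max_range:.1f} Hz exceeds Nyquist "
            f"{fs / 2:.1f} Hz (range {max_range:.2f} m beyond unambiguous span)"
        )

    gains = scene.gains(q)
    psis = scene.phase_offsets(q)
    fast = np.arange(n)

    samples = np.zeros((n_ramps, q, n), dtype=complex)
    chan_factor = (gains * np.exp(1j * psis))[None, :, None]
    for ranges, amp in scatterers:
        f_b = beat_coeff * ranges  # per ramp
        # phase[m, n] = 2 pi f_b[m] n / fs + 4 pi R[m] / lambda
        ph = (
            2.0 * np.pi * f_b[:, None] * fast[None, :] / fs
            + 4.0 * np.pi * ranges[:, None] / lam
        )
        samples += amp * chan_factor * np.exp(1j * ph)[:, None, :]

    rng = np.random.default_rng(scene.seed)
    if scene.noise_sigma > 0:
        noise = rng.normal(0.0, scene.noise_sigma, samples.shape)
        if config.acquisition_mode is AcquisitionMode.IQ:
            noise = noise + 1j * rng.normal(0.0, scene.noise_sigma, samples.shape)
        samples = samples + noise

    if config.acquisition_mode is AcquisitionMode.I_ONLY:
        samples = samples.real.copy()

    return RawCapture(
        samples=samples,
        config=config,
        start_time=0.0,
        n_ramps=n_ramps,
    )


def emulate_reference_monitor(
    truth: GroundTruth,
    smoothing_window: float = 30.0,
    output_rate: float = 1.0,
) -> RateSeries:
    """Emulate the cable-based monitor's slow, heavily averaged rate output.

    The configured true rate (sentinel mapped to 0 bpm) is averaged over a
    trailing window of *smoothing_window* seconds and resampled to
    *output_rate*.  An apnea shorter than the window therefore shows only
    as a partial dip, never as zero — the behaviour that makes such
    monitors miss brief apneas.
    """
    if not smoothing_window > 0:
        raise ValueError(f"smoothing_window must be positive, got {smoothing_window}")
    if not output_rate > 0:
        raise ValueError(f"output_rate must be positive, got {output_rate}")

    t = truth.timestamps
    r = np.where(np.isfinite(truth.true_rate.rate), truth.true_rate.rate, 0.0)
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else truth.profile.duration
    w = max(1, int(round(smoothing_window * fs)))
    # trailing (causal) moving average with a growing warm-up window
    csum = np.concatenate(([0.0], np.cumsum(r)))
    idx = np.arange(r.size)
    lo = np.maximum(0, idx - w + 1)
    smoothed = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)

    out_t = np.arange(t[0], t[-1] + 1e-9, 1.0 / output_rate)
    out_r = np.interp(out_t, t, smoothed)
    # the reference never reports outside its plausible band; clip softly
    out_r = np.clip(out_r, 0.0, None)
    band = (0.0, 300.0)
    return RateSeries(timestamps=out_t, rate=out_r, source=RateSource.REFERENCE, band=band)
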