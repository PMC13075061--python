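# Methods

## Signal model

The package works entirely in the de-chirped (beat-signal) domain. For a
linear FMCW ramp of bandwidth B swept over T_ramp and sampled at f_s, a
point scatterer at range R contributes, at fast-time sample n of ramp m on
receive channel q,

    s[m, q, n] = A · g_q · exp( j( 2π f_b n / f_s + 4π R(m)/λ + ψ_q ) ),
    f_b = 2 R B / (c · T_ramp),

with channel gain g_q and phase offset ψ_q. The breathing subject is one
such scatterer whose range follows the slow-time chest position
x(t) = R₀ + resp(t) + cardiac(t) + motion(t); clutter scatterers are fixed.
In `i_only` acquisition only the real part is kept, reproducing a receiver
that digitizes the in-phase channel alone; processing then uses the
positive-frequency half spectrum, accepting conjugate-image leakage as part
of that limitation. No RF-level propagation, antenna pattern, multipath or
I/Q imbalance is modeled.

Default front-end parameters: 24.125 GHz carrier (λ ≈ 12.43 mm), 250 MHz
bandwidth (range resolution c/2B ≈ 0.5996 m), 128 samples per ramp at
8192 Hz (T_ramp = 15.625 ms), 32 Hz ramp repetition, 4 receive channels,
0.4 m standoff. A `wavelength_override` lets the derived maximum
unambiguous speed be computed with a nominal 12.5 cm wavelength (giving the
round 1 m/s figure) instead of the physical carrier wavelength; the default
is always the physical value.

## Ground-truth motion generator

Sampled at the ramp rate, at ramp centers.

- **Respiration**: amplitude d (default 1.5 mm) with instantaneous
  frequency rate(t)/60; the rate is a constant or a user function (the
  built-in scenarios drift sinusoidally 80–90 bpm with a 300 s period so
  correlation statistics are well defined). Waveforms: pure sinusoid, or an
  asymmetric raised cosine (inhale 35% of the cycle) closer to real
  pneumograms. Inside apnea intervals the respiratory term is exactly zero;
  cardiac and gross motion persist.
- **Cardiac micro-motion**: 0.1 mm sinusoid at 200 bpm (piglet-like). It is
  a confounder only, not an estimation target.
- **Gross motion**: per episode, a Gaussian random walk band-limited to
  0.15–4 Hz, scaled to the episode's displacement standard deviation and
  edge-tapered. The lower band edge is deliberate: an unfiltered walk puts
  nearly all its power below 0.1 Hz, where the respiration band-pass removes
  it, which would make "gross movement" invisible to the pipeline; real limb
  and body movements carry velocity content throughout the low-frequency
  band. The `high_motion` scenario uses 30 s episodes separated by 15 s of
  calm (about two thirds of the session) with 8 mm standard deviation —
  centimeter-scale peak excursions, an order of magnitude above breathing,
  representing a subject that moves through most of the recording.
- **Scene**: one static clutter scatterer at 0.9 m with relative amplitude
  0.5 by default (an incubator-lid-like reflection inside the range of
  interest), white Gaussian noise of σ = 0.3 per real sample relative to
  unit target amplitude (≈10 dB per-sample SNR before the ~21 dB fast-time
  processing gain), and optional per-channel gain/phase mismatch.

All randomness is seeded; identical inputs give bit-identical captures.

### Emulated reference monitor

The cable-bound comparison monitor is modeled as a trailing moving average
(default 30 s) of the true rate, resampled to 1 Hz, with the undefined-rate
sentinel mapped to 0 bpm inside the average. This reproduces the clinically
observed behaviour that such monitors, with their long measurement windows,
show only a delayed partial dip during a short apnea — a 14 s pause against
a 30 s window cannot drive the displayed rate below (1 − 14/30) of baseline.
The true window length of any specific commercial monitor is not public;
both window and output rate are configurable.

## Processing chain choices

- **Per-ramp linear detrending** over fast time removes DC and linear
  components that alias into the lowest beat frequencies, i.e. apparent
  close-range returns. Applying it across ramps instead would act on the
  slow-time (motion) axis and is rejected because the correction must
  precede the range transform.
- **Range transform**: Hann window, zero-padding factor 4. The subject at
  0.4 m falls below one un-padded 0.6 m bin; padding interpolates the peak
  so the gate lands on a stable bin. Only the non-negative-range half
  spectrum is kept.
- **Target detection**: argmax of the ramp- and channel-averaged magnitude
  inside a 0.2–1.2 m range of interest (standoff ± mattress geometry), with
  a no-target error when the maximum is below 3× the median bin magnitude.
  Ties break to the lower bin. Note that with the default scene the gate
  settles at 0.75 m, between subject and clutter, because the two window
  lobes merge at this range resolution; the demodulated phase there still
  tracks chest motion (scaled by the clutter phasor), which the end-to-end
  tests verify is sufficient for rate recovery.
- **Phase extraction**: complex angle at the gated bin, unwrapped per
  channel with the conventional π jump threshold — valid because the
  maximum unambiguous speed bounds the per-ramp phase step for breathing
  motion.
- **Channel combination**: mean-center each channel, sign-align to channel
  0 by correlation sign, average with equal weights. Simplest deterministic
  rule; SNR weighting was considered and left out of the baseline.
- **Respiration filter**: 4th-order Butterworth band-pass 0.1–2.0 Hz
  (6–120 bpm) applied forward-backward (zero phase). The band covers
  piglet-like rates of 80–90 bpm with margin and excludes their cardiac
  line (> 2.5 Hz). Passband droop at 1.4 Hz is ~3.5%; attenuation one
  octave outside the band exceeds 20 dB.
- **Breath peaks**: `scipy.signal.find_peaks` with prominence ≥ 0.5× the
  MAD-scale amplitude of the filtered trace, plus a height floor of half
  that threshold. The height floor exists because global peak prominence is
  inflated for tiny bumps inside a respiratory pause (the band-pass
  undershoot at the pause edges provides deep far-away saddles); requiring
  the peak to rise above the zero baseline of the band-passed trace rejects
  them without touching genuine breaths. Peak times are refined by
  parabolic interpolation around each maximum: the 31.25 ms slow-time grid
  would otherwise quantize inter-breath intervals coarsely enough to bias
  rates by ~2 bpm at 85 bpm.
- **Rate**: 60 / median inter-peak interval in a 30 s window stepped by
  1 s, centered timestamps. The median tolerates a single missed or
  spurious peak. Windows with fewer than two peaks, or a median interval
  outside 6–180 bpm, report an explicit NaN sentinel — never zero, since
  0 bpm is a meaningful apnea value.
- **Apnea events**: intervals ≥ 10 s (configurable floor) with no breath
  peak and short-time RMS (1 s window) of the respiration-band phase below
  30% of baseline. The baseline is the median of the RMS trace over the
  recording — a robust "running" level as long as the subject breathes most
  of the time; a recording that is mostly apneic would need an external
  baseline. The floor is configurable because overly sensitive detection of
  short physiological pauses is undesirable in practice.
- **Gross-motion intervals are not masked**: the baseline pipeline
  deliberately lets movement corrupt the rate estimate, reproducing the
  known weakness of simple range-gated phase processing under body motion;
  artifact classification and beamforming are out of scope.

## Agreement evaluation

Both rate series are linearly interpolated onto a common 1 Hz grid over
their overlap; sentinel gaps wider than twice the native sampling interval
are not bridged. The lag (±30 s, 1 s steps) maximizing Pearson correlation
of valid pairs aligns radar to reference, ties breaking toward smaller
|lag|. On the aligned pairs: R² is the squared Pearson correlation;
Bland–Altman statistics are the mean difference (radar − reference) and
mean ± 1.96 sample standard deviations (n−1); relative differences are
100·(radar − reference)/pair-mean. Sentinel pairs are dropped listwise;
zero-mean pairs are skipped with a warning.

## What the simulation does and does not show

The generator reproduces the geometry, displacement scales, rates, noise
and clutter structure of incubator monitoring, so passing tests demonstrate
that the processing chain is correct and that its qualitative behaviours
(apnea sensitivity, reference-monitor apnea blindness, motion degradation)
follow from the physics. It does not reproduce real tissue scattering,
antenna patterns, multipath inside an incubator, breathing-waveform
variability, or the actual artifact statistics of a living animal — so the
near-perfect calm-session agreement (R² ≈ 0.999) is an upper bound set by
the model's cleanliness, not a claim about field performance, where
moderate-to-high correlations are the realistic outcome.

## Numerical notes and problem sizes

Zero-phase filtering uses second-order sections for stability. The moving
mean of x² is clipped at zero before the square root (it can go
epsilon-negative on exactly-zero input). Target-bin ties break low;
sign-alignment treats zero correlation as +1. Captures are float64/
complex128; a 1000 s four-channel capture is ~131 MB and processes in
~10 s. The test suite and the acceptance script use 120–1000 s sessions
and a 10-seed suite for the motion-ordering property, sizes chosen to make
the statistics stable while keeping a full run around a minute.

## Known limitations

- Single breathing scatterer; no range–angle discrimination, beamforming,
  heart-rate extraction or SpO₂.
- The apnea baseline assumes mostly-breathing recordings.
- I-only processing accepts conjugate-image interference by design; full
  I/Q is available via the acquisition-mode switch.
- Agreement statistics assume both series cover the same session with
  bounded clock offset (≤ max_lag).
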