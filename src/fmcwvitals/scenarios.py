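"""Built-in simulation scenarios emulating incubator monitoring sessions.

Two canonical conditions recur throughout the tests and the demo:

* ``low_motion`` — a sedated, calmly sleeping subject breathing around
  80-90 bpm with a slow rate drift; the condition under which radar and
  reference monitor agree closely.
* ``high_motion`` — the same subject with repeated gross-motion episodes
  (wake-up-like limb/body movements) that corrupt the phase trace and
  degrade the radar rate estimate.

Rates drift sinusoidally within 80-90 bpm so that correlation-based
agreement statistics are well defined.  Displacement amplitudes (1.5 mm
respiratory, 0.1 mm cardiac) and the 0.4 m standoff are the simulator
defaults.
"""

from __future__ import annotations

import numpy as np

from .simulator import MotionProfile, SceneConfig

__all__ = ["drifting_rate", "low_motion", "high_motion", "apnea_scenario"]


def drifting_rate(mean_bpm: float = 85.0, swing_bpm: float = 5.0, period_s: float = 300.0):
    """A slowly drifting breathing rate, ``mean + swing * sin(2 pi t / period)``."""

    def rate(t: np.ndarray) -> np.ndarray:
        return mean_bpm + swing_bpm * np.sin(2.0 * np.pi * np.asarray(t) / period_s)

    return rate


def low_motion(duration: float = 1000.0, seed: int = 0) -> tuple[MotionProfile, SceneConfig]:
    """Calm-sleep session: drifting 80-90 bpm, no gross motion."""
    profile = MotionProfile(
        duration=duration,
        respiration_rate=drifting_rate(),
        waveform="asymmetric",
    )
    scene = SceneConfig(seed=seed)
    return profile, scene


def high_motion(duration: float = 300.0, seed: int = 0) -> tuple[MotionProfile, SceneConfig]:
    """Movement-intensive session: same breathing plus gross-motion episodes.

    Gross-motion episodes of 30 s, separated by 15 s of calm, cover about
    two thirds of the session — a subject moving through most of the
    recording, the condition under which such sessions get aborted.  Each
    episode is a band-limited random walk with 8 mm standard deviation
    (peak excursions of a few cm): an order of magnitude above the ~1.5 mm
    breathing displacement, with velocity content overlapping the
    respiration band so the interference lands where breathing is read.
    """
    episodes = []
    start = 20.0
    while start + 35.0 < duration:
        episodes.append((start, start + 30.0, 8.0))
        start += 45.0
    profile = MotionProfile(
        duration=duration,
        respiration_rate=drifting_rate(),
        waveform="asymmetric",
        motion_intervals=episodes,
    )
    scene = SceneConfig(seed=seed)
    return profile, scene


def apnea_scenario(
    duration: float = 120.0,
    apnea_start: float = 50.0,
    apnea_duration: float = 14.0,
    seed: int = 0,
) -> tuple[MotionProfile, SceneConfig]:
    """Calm breathing with a single respiratory pause (default 14 s)."""
    profile = MotionProfile(
        duration=duration,
        respiration_rate=85.0,
        waveform="asymmetric",
        apnea_intervals=[(apnea_start, apnea_start + apnea_duration)],
    )
    scene = SceneConfig(seed=seed)
    return profile, scene
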