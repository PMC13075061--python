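import numpy as np
import pytest

from fmcwvitals import (
    MotionProfile,
    PipelineConfig,
    RadarConfig,
    SceneConfig,
    generate_displacement,
    synthesize_capture,
)


@pytest.fixture
def iq_config() -> RadarConfig:
    return RadarConfig(acquisition_mode="iq")


@pytest.fixture
def default_config() -> RadarConfig:
    return RadarConfig()


@pytest.fixture
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def clean_scene() -> SceneConfig:
    """Noiseless, clutter-free scene for closed-form oracles."""
    return SceneConfig(clutter_targets=(), noise_sigma=0.0)


def make_breathing_capture(
    config: RadarConfig,
    duration: float = 30.0,
    rate_bpm: float = 85.0,
    amplitude_mm: float = 1.0,
    cardiac_amplitude_mm: float = 0.0,
    scene: SceneConfig | None = None,
    seed: int = 0,
):
    """Convenience: sinusoidal breather at the default standoff."""
    profile = MotionProfile(
        duration=duration,
        respiration_rate=rate_bpm,
        respiration_amplitude_mm=amplitude_mm,
        cardiac_amplitude_mm=cardiac_amplitude_mm,
    )
    scene = scene or SceneConfig(clutter_targets=(), noise_sigma=0.0, seed=seed)
    truth = generate_displacement(profile, config, seed=seed)
    capture = synthesize_capture(config, scene, truth)
    return truth, capture
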