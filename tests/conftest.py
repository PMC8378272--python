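import numpy as np
import pytest

from cardiomps import AnalysisConfig
from cardiomps.synth import BeatTemplateParams, SimConfig, simulate_trace


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def clean_train():
    """Noise-free 1-Hz calcium beat train (30 beats), with its ground truth."""
    cfg = SimConfig(noise_sd=0.0, bleach_per_s=0.0, spontaneous_rate_hz=1.0, rr_jitter=0.0)
    return simulate_trace(BeatTemplateParams(), cfg, rhythm="spontaneous", length_s=30.0)


@pytest.fixture
def noisy_train():
    """Realistic 30-s spontaneous calcium recording (noise, bleaching)."""
    cfg = SimConfig(seed=11, noise_sd=0.02, spontaneous_rate_hz=0.75)
    return simulate_trace(
        BeatTemplateParams(), cfg, rhythm="spontaneous", length_s=30.0,
        rng=np.random.default_rng(11),
    )
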