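import numpy as np
import pytest

from chirplearn.audio import AudioClip
from chirplearn.synth import SceneConfig, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sine_clip(freq_hz: float, seconds: float, sample_rate: int,
              amplitude: float = 0.5) -> AudioClip:
    t = np.arange(int(round(seconds * sample_rate))) / sample_rate
    return AudioClip(amplitude * np.sin(2 * np.pi * freq_hz * t), sample_rate)


@pytest.fixture(scope="session")
def small_corpus():
    """Six-species flat mini-corpus shared by tests that only need data."""
    return generate_corpus(SceneConfig(n_species=6, top_count=12, zipf_s=0.3,
                                       seed=3))


@pytest.fixture(scope="session")
def flat_corpus():
    """Ten-species corpus with a near-flat count distribution; learnable."""
    return generate_corpus(SceneConfig(n_species=10, top_count=40, zipf_s=0.3,
                                       seed=1))
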