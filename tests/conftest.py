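import numpy as np
import pytest

from ecgscope.dataset import split_registry
from ecgscope.synthetic import EASY_NOISE, sample_identity, synth_recording, synth_registry


@pytest.fixture(scope="session")
def easy_registry():
    """Two-database easy-regime registry (clean, no drift): 24 identities
    at 128 Hz plus 16 at 256 Hz, 64 s per identity."""
    return synth_registry(2, [24, 16], [128.0, 256.0], 12345,
                          duration_s=64.0, noise=EASY_NOISE, drift_rate=0.0)


@pytest.fixture(scope="session")
def easy_split(easy_registry):
    return split_registry(easy_registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free, jitter-free periodic recording at 128 Hz."""
    morph = sample_identity(7)
    morph.rr_jitter_sd = 0.0
    from ecgscope.synthetic import NoiseSpec
    return synth_recording(morph, NoiseSpec(0.0, 0.0), 30.0, 128.0,
                           rng_seed=1, identity_id="clean"), morph
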