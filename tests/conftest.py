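import numpy as np
import pytest

from keranet.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A tiny separable synthetic corpus shared across tests (10+10, 48px)."""
    out = tmp_path_factory.mktemp("corpus")
    cfg = SynthConfig(n_ak=10, n_nak=10, image_size=(48, 48),
                      separability=1.0, seed=7, out_dir=out)
    index = generate_corpus(cfg)
    return cfg, index


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
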