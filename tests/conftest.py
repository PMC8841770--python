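import numpy as np
import pytest

from eitclean import build_sensitivity


@pytest.fixture(scope="session")
def model():
    """Shared ~800-element disk phantom (deterministic, ~0.3 s to build)."""
    return build_sensitivity(800)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
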