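import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50, database=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A small but structurally complete architecture for fast tests."""
    from ltnet.model import LTBlockConfig, LTNetConfig

    return LTNetConfig(
        input_channels=3, input_size=(16, 16), stem_channels=8,
        blocks=[LTBlockConfig(channels=16, n_convbn=2, se_ratio=4, stride=2),
                LTBlockConfig(channels=12, n_convbn=1, se_ratio=4, stride=2)],
        n_classes=3)
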