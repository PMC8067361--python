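"""Shared fixtures: reduced-size templates so suites stay fast."""

import numpy as np
import pytest
from hypothesis import settings

from manduca import MothTemplate

# deterministic hypothesis runs
settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_template() -> MothTemplate:
    """Reduced Kenyon-cell count; all other parameters at study defaults."""
    return MothTemplate(n_kc=500)


@pytest.fixture(scope="session")
def tiny_template() -> MothTemplate:
    """Very small network for fast structural tests."""
    return MothTemplate(n_glomeruli=20, n_kc=120, n_odor_targets=8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
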