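import numpy as np
import pytest


@pytest.fixture
def rng() -> np.random.Generator:
    """Fresh deterministic generator for each test."""
    return np.random.default_rng(12345)


@pytest.fixture
def make_rng():
    """Factory for seeded generators, for tests sweeping many seeds."""

    def _make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)

    return _make
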