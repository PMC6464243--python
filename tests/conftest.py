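import numpy as np
import pytest

from mirdap.embedding import SkipgramConfig
from mirdap.pipeline import PipelineInputs
from mirdap.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small, fast study conditions for smoke tests (not the benchmark)."""
    return SyntheticConfig(n_diseases=12, n_mirnas=18, n_clusters=3, seed=5)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate_bundle(tiny_config)


@pytest.fixture(scope="session")
def tiny_inputs(tiny_bundle):
    return PipelineInputs.from_bundle(tiny_bundle)


@pytest.fixture(scope="session")
def fast_skipgram() -> SkipgramConfig:
    """Low-cost embedding settings for smoke tests."""
    return SkipgramConfig(min_count=2, size=16, iterations=3, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
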