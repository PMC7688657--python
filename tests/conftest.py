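import numpy as np
import pytest

from stedpuncta.config import PipelineConfig
from stedpuncta.synth import SynthConfig


@pytest.fixture
def pcfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def scfg() -> SynthConfig:
    return SynthConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
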