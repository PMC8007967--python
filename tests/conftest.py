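import numpy as np
import pytest

from fruitscape.pipeline import PipelineConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def default_report(default_config, default_dataset):
    return run_pipeline(default_config, default_dataset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
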