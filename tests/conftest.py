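import numpy as np
import pytest

from tallsurv.evaluation import PipelineConfig
from tallsurv.synthetic import SyntheticConfig, generate_cohort

# small grid keeps classifier fits cheap in unit tests
FAST_GRID = {"max_depth": [2], "learning_rate": [0.3], "n_estimators": [50]}


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Desk-size cohort: 60 samples x 200 genes, strong two-subgroup signal."""
    return SyntheticConfig(n_samples=60, n_genes=200, n_informative=30, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    return PipelineConfig(seed=11, classifier_grid=dict(FAST_GRID), n_reps=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
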