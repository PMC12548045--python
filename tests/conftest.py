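import pytest

from genesieve.criteria import CRITERIA
from genesieve.gateway import DEFAULT_RUBRIC, default_templates
from genesieve.pipeline import PipelineConfig, run_pipeline
from genesieve.simulate import StudyConfig, generate_study


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def rubric():
    return DEFAULT_RUBRIC


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(n_genes=120, n_relevant=12, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_pipeline_result():
    """One small but complete pipeline run shared across tests."""
    config = PipelineConfig(study=StudyConfig(n_genes=150, n_relevant=15,
                                              seed=3))
    return run_pipeline(config)


def make_scores(values):
    """Criterion -> score mapping from a plain list (ordered by scheme)."""
    return dict(zip(CRITERIA, values))
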