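import pytest

from ihctps.experiments import build_training_table, train_study_classifier
from ihctps.features import train_classifier
from ihctps.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def training_table(pipeline_config):
    """Labelled feature table from the study-budget training set (30 patches / 10 cases)."""
    return build_training_table(pipeline_config, seed=11)


@pytest.fixture(scope="session")
def trained_model(pipeline_config, training_table):
    """Classifier trained once on the study-budget table, shared across tests."""
    return train_classifier(training_table, pipeline_config.forest)
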