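import pytest

from hboc_triage import SimulationConfig, default_panel, generate_cohort
from hboc_triage.classifier import ClassifierConfig
from hboc_triage.qc_filters import QcThresholds


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def qc_defaults():
    return QcThresholds()


@pytest.fixture(scope="session")
def clf_defaults():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared across read-only tests."""
    config = SimulationConfig(n_cancer=40, n_high_risk=8, seed=11)
    patients, table, truth = generate_cohort(config)
    return config, patients, table, truth
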