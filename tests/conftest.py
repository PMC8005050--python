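import numpy as np
import pytest

from neckcast.device_models import AWT, EOBS
from neckcast.pipeline import build_labeled_dataset, prepare_features
from neckcast.synthetic_data import ScenarioConfig, generate_truth


@pytest.fixture(scope="session")
def default_scenario():
    """The standard well-separated 3-individual campaign, seed fixed."""
    return ScenarioConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_scenario):
    return generate_truth(default_scenario)


@pytest.fixture(scope="session")
def eobs_dataset(default_scenario, default_truth):
    return build_labeled_dataset(default_scenario, EOBS, default_truth)


@pytest.fixture(scope="session")
def awt_dataset(default_scenario, default_truth):
    return build_labeled_dataset(default_scenario, AWT, default_truth)


@pytest.fixture(scope="session")
def eobs_table(eobs_dataset):
    return prepare_features(eobs_dataset, EOBS, 30, subsample_seed=11)


@pytest.fixture(scope="session")
def awt_table(awt_dataset):
    return prepare_features(awt_dataset, AWT, 30, subsample_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_scenario():
    """One individual, ten minutes — cheap enough for unit tests."""
    return ScenarioConfig(individuals=["solo"], session_length=600.0, seed=3)
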