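import numpy as np
import pytest

from confboot.pipeline import (
    DEFAULT_TASK,
    default_schedule,
    fit_confidence,
    pretrain_generator,
)
from confboot.toytask import make_task, split_complexes


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def task():
    """The default study task: 4 train clusters, 2 held-out, 10 complexes each."""
    return make_task(**DEFAULT_TASK, seed=0)


@pytest.fixture(scope="session")
def pretrained(task, schedule):
    """Generator pretrained with plain DSM on the training clusters."""
    return pretrain_generator(task, schedule, seed=0)


@pytest.fixture(scope="session")
def learned_conf(task, pretrained, schedule):
    return fit_confidence(task, pretrained, schedule, seed=0)


@pytest.fixture(scope="session")
def heldout_complexes(task):
    _, heldout = split_complexes(*task)
    return heldout


@pytest.fixture(scope="session")
def train_complexes(task):
    train, _ = split_complexes(*task)
    return train


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
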