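import pytest

from rqcontrol import TwinParams
from rqcontrol.experiments import run_benchmark, train_default_gain_model
from rqcontrol.gain_model import build_training_set, generate_training_corpus


@pytest.fixture(scope="session")
def params():
    return TwinParams()


@pytest.fixture(scope="session")
def corpus(params):
    """Simulated historical fermentations (2 strategies x 3 growth rates)."""
    return generate_training_corpus(params, seed=1)


@pytest.fixture(scope="session")
def training_set(corpus, params):
    return build_training_set(corpus, params)


@pytest.fixture(scope="session")
def gain_model(params):
    return train_default_gain_model(params, seed=1)


@pytest.fixture(scope="session")
def benchmark(params):
    """The full three-strategy, five-seed closed-loop comparison."""
    return run_benchmark(seed=1, n_seeds=5, params=params)
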