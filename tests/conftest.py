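import numpy as np
import pytest

from screensim import ScenarioConfig, load_model, run_replications


@pytest.fixture(scope="session")
def model():
    """The bundled default screening-center model."""
    return load_model()


@pytest.fixture(scope="session")
def mm1_model():
    """Single-server queue wrapped in zero-duration entry/exit steps."""
    cfg = {
        "stations": {
            "A": {"capacity": "unbounded"},
            "B": {"capacity": 1},
            "V": {"capacity": "unbounded"},
        },
        "distributions": {"B": {"family": "EXPO", "params": [1.0]}},
        "types": {"X1": {"sex": "female", "age_band": "all", "proportion": 1.0}},
        "routes": {"X1": ["A", "B", "V"]},
    }
    return load_model(cfg)


@pytest.fixture(scope="session")
def baseline_summary(model):
    """One 50-replication baseline run shared by the slower tests."""
    return run_replications(ScenarioConfig(volume=30, replications=50, base_seed=12345), model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160901)
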