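import numpy as np
import pytest
import yaml

from s2w.engine import SimulationEngine
from s2w.model import build_model, default_model_file


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def engine(model):
    return SimulationEngine(model)


@pytest.fixture(scope="session")
def model_raw():
    with open(default_model_file()) as fh:
        return yaml.safe_load(fh)


@pytest.fixture(scope="session")
def frictionless_engine(model_raw):
    """Engine on a variant without joint limits or passive damping, for
    energy-conservation checks."""
    raw = yaml.safe_load(yaml.safe_dump(model_raw))
    for j in raw["joints"]:
        j["limit_stiffness"] = 0.0
        j["limit_damping"] = 0.0
        j["passive_damping"] = 0.0
    return SimulationEngine(build_model(raw))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
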