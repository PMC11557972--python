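import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from apisomnia import synth, ingest


@pytest.fixture(scope="session")
def default_config():
    return synth.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def default_experiment(default_config):
    return synth.simulate_experiment(default_config)


@pytest.fixture(scope="session")
def default_series(default_experiment):
    return ingest.to_sleep_series(default_experiment)


def make_series(hours, values, cage_id="X1", condition="LD", replicate=1):
    hours = np.asarray(hours, dtype=float)
    return ingest.SleepSeries(
        cage_id=cage_id,
        condition=condition,
        replicate_index=replicate,
        hours=hours,
        percent_asleep=np.asarray(values, dtype=float),
        percent_alive=np.full(len(hours), 100.0),
    )
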