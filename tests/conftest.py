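import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epilineage.synthetic_data import (
    SimConfig,
    generate_bulk,
    signature_from_truth,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bulk_sim():
    """Default-condition bulk simulation with planted signature genes."""
    cfg = SimConfig(seed=101)
    counts, truth = generate_bulk(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def planted_signature(bulk_sim):
    _, _, truth = bulk_sim
    return signature_from_truth(truth)
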