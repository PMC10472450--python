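import numpy as np
import pytest

from bcgkit import RunConfig, SimConfig, detect_ijk, simulate_record


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free simulation: ground truth is exact and filters are idle."""
    return SimConfig(
        duration_s=30.0,
        noise_sigma=0.0,
        resp_amplitude=0.0,
        artifact_rate_per_min=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def clean_sim(clean_config):
    return simulate_record(clean_config)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition record (60 s, 60 bpm, moderate noise)."""
    return simulate_record(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_detection(default_sim):
    """Full detection on the default record, shared across test modules."""
    record, truth = default_sim
    ann, report = detect_ijk(record, RunConfig(rng_seed=11), return_report=True)
    return record, truth, ann, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
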