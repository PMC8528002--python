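import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qpa.simulate import SimulationConfig, default_strains, simulate_experiment

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 2-strain x 3-replicate simulated experiment with its manifest."""
    strains = {k: v for k, v in list(default_strains().items())[:2]}
    cfg = SimulationConfig(
        strains=strains, n_replicates=3, events_per_acquisition=3000, seed=7
    )
    root = tmp_path_factory.mktemp("bundle")
    return simulate_experiment(cfg, root)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
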