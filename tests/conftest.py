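import numpy as np
import pytest

from vulturenet.pipeline import build_networks, run_pipeline
from vulturenet.permutation import AnalysisConfig
from vulturenet.simulate import SimConfig, simulate, study_config_for


@pytest.fixture()
def rng():
    return np.random.default_rng(20210601)


@pytest.fixture(scope="session")
def small_sim():
    """A short simulated season, shared across tests (read-only)."""
    cfg = SimConfig(n_individuals=12, n_days=15, rng_seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_sim_networks(small_sim):
    return build_networks(
        small_sim.fixes, small_sim.roosts, study_config_for(small_sim.config)
    )


@pytest.fixture(scope="session")
def small_sim_report(small_sim):
    return run_pipeline(
        small_sim.fixes,
        small_sim.roosts,
        study_config_for(small_sim.config),
        AnalysisConfig(n_iterations=300, rng_seed=7),
    )
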