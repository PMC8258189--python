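import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import thermoscape as ts

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_network():
    return ts.generate_network(n_catchments=80, n_regions=2, seed=7)


@pytest.fixture(scope="session")
def quiet_climate():
    """Deterministic climate: no noise, so seasonal structure is exact."""
    return ts.ClimateConfig(noise_sd_C=0.0)


@pytest.fixture(scope="session")
def small_env(small_network, quiet_climate):
    return ts.generate_environment(small_network, quiet_climate, seed=11)


@pytest.fixture(scope="session")
def niche_truth():
    return ts.NicheConfig().truth("Salmo synthetica")


@pytest.fixture
def adult_tpc():
    return ts.TPC(ts.ThermalTraits("s", "adult", ct_min=0.0, t_opt=16.0, ct_max=25.0))


@pytest.fixture
def toy_scores_labels():
    scores = np.array([0.9, 0.8, 0.3, 0.2])
    labels = np.array([1, 1, 0, 0])
    return scores, labels
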