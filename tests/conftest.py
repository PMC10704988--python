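import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated study shared by read/annotation tests."""
    from rbpflow.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(
            seed=42, n_genes=12, n_planted_peaks=4,
            n_deg_up=3, n_deg_down=2, n_lncrnas=4, n_cis_pairs=2,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
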