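import pytest

from cenreg.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One default-noise synthetic dataset shared across tests."""
    return simulate_all(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        seed=1,
        n_tus=20,
        n_direct_targets=12,
        frac_repressed=0.25,
        detection_power=1.0,
        jitter_sd=0.0,
        peak_fpr=0.0,
        ns_frac=0.0,
        lfc_effect_sd=0.05,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return simulate_all(noiseless_config)
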