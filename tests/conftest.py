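import pytest

from fermgas import HeadspaceConfig
from fermgas.synthetic import SimulationConfig, simulate_run


@pytest.fixture(scope="session")
def headspace() -> HeadspaceConfig:
    return HeadspaceConfig()


@pytest.fixture(scope="session")
def noiseless_run():
    """One noiseless synthetic run with the full gas chain, shared across tests."""
    return simulate_run(SimulationConfig(seed=7, noise_cv=0.0))


@pytest.fixture(scope="session")
def ideal_run():
    """Noiseless run with the alanine/EPS branches off: exact acetate stoichiometry."""
    cfg = SimulationConfig(
        seed=7, noise_cv=0.0, f_alanine=0.0, f_eps=0.0, eps_stress_boost=0.0
    )
    return simulate_run(cfg, include_gas=False)
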