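import pytest

from dmrscape.synthetic import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down cohort: full sample layout, 10x fewer DMRs."""
    return SimConfig(n_dmrs_per_pattern=(67, 65, 137), n_null_probes=2000, seed=1)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Full default cohort (672/650/1375 DMRs, 98 tumors + 4 normals)."""
    return simulate_all(SimConfig(seed=1))
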