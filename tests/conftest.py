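import numpy as np
import pytest

import ctmix


@pytest.fixture(scope="session")
def base_small():
    """Desk-scale cell-separated base data shared across tests."""
    return ctmix.generate_base_profiles(
        ctmix.BaseProfileConfig(n_probes=4000, seed=7)
    )


@pytest.fixture(scope="session")
def scenario1_small():
    """Scenario-1 preset (distinct cell-type effect distributions)."""
    return ctmix.load_scenario("scenario1", seed=11)


@pytest.fixture(scope="session")
def sim1(base_small, scenario1_small):
    """One confounded replication on the small base data."""
    return ctmix.run_scenario(base_small, scenario1_small)


@pytest.fixture(scope="session")
def null_sim():
    """Pure-null mixture: no DMSs, no composition-phenotype link."""
    base = ctmix.generate_base_profiles(
        ctmix.BaseProfileConfig(n_probes=20_000, seed=21)
    )
    scenario = ctmix.ScenarioConfig(
        name="null",
        s=0,
        mu_k=(0.0, 0.0),
        sigma_k=(0.0, 0.0),
        sigma_jk=0.1,
        rho=100.0,
        delta_alpha=(0.0, 0.0),
        seed=22,
    )
    return ctmix.run_scenario(base, scenario)
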