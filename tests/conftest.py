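import pytest

from fermkin import BagScenario, GasScenario, IncubationConstants


@pytest.fixture
def constants() -> IncubationConstants:
    return IncubationConstants()


@pytest.fixture
def clean_gas_scenario() -> GasScenario:
    """One substrate, no noise, no replicate variation: exact round trips."""
    return GasScenario(
        substrates={"PR_early": (181.8, 8.3, 1.62)},
        n_replicates=1,
        n_blanks=0,
        replicate_cv=(0.0, 0.0, 0.0),
        noise_sd_psi=0.0,
        seed=7,
    )


@pytest.fixture
def noiseless_bag_scenario() -> BagScenario:
    return BagScenario(ddm_noise_sd=0.0, seed=11)
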