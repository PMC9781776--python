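import pytest

from sugarnet import load_reference_network
from sugarnet.orthology import merge_orthogroup_sets
from sugarnet.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def net():
    return load_reference_network()


@pytest.fixture(scope="session")
def scenario(net):
    """Default study-condition scenario (three species, seeded)."""
    return generate_scenario(net, ScenarioConfig(seed=11, discordance=0.2))


@pytest.fixture(scope="session")
def noiseless_scenario(net):
    """Scenario with expression noise disabled, for exact-recovery checks."""
    return generate_scenario(
        net,
        ScenarioConfig(seed=11, expression_sigma=0.0, block_sigma=0.0),
    )


@pytest.fixture(scope="session")
def merged_groups(scenario):
    return merge_orthogroup_sets(scenario.orthomcl, scenario.orthofinder)
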