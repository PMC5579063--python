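import pytest

from drugfams.core import build_profiles, classify_interactions
from drugfams.synth import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world, shared read-only across the session."""
    return generate_world(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def profiles(world):
    interactions = classify_interactions(world.activities)
    return build_profiles(interactions, world.family_table)


@pytest.fixture(scope="session")
def small_world():
    """A cheaper world for tests that regenerate or permute repeatedly."""
    cfg = SyntheticConfig(n_proteins=150, n_families=12, n_drugs=24, seed=7)
    return generate_world(cfg)
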