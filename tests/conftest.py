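import pytest

from fcumap import fixtures, registry


@pytest.fixture(scope="session")
def demo_taxonomy():
    return fixtures.build_demo_taxonomy()


@pytest.fixture(scope="session")
def demo_thesaurus():
    return fixtures.build_demo_thesaurus()


@pytest.fixture()
def demo_set():
    return fixtures.build_demo_mapping_set()


@pytest.fixture(scope="session")
def reg():
    return registry()


@pytest.fixture(scope="session")
def random_bundle():
    """A mid-sized seeded random taxonomy/thesaurus/assertion bundle."""
    params = fixtures.GeneratorParams(seed=42, n_taxa=150, n_usages=40)
    return fixtures.generate_random(params)
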