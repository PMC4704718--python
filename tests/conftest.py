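import pytest

from parabsa.fixture import (
    StudyConfig,
    build_parents,
    build_pool,
    build_reference,
    build_segregants,
    write_fixture,
)


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig(rng_seed=0)


@pytest.fixture(scope="session")
def reference(study_config):
    return build_reference(study_config)


@pytest.fixture(scope="session")
def parents(study_config, reference):
    return build_parents(study_config, reference)


@pytest.fixture(scope="session")
def segregants_and_table(study_config, reference, parents):
    table, segregants = build_segregants(study_config, reference, parents)
    return table, segregants


@pytest.fixture(scope="session")
def genotype_table(segregants_and_table):
    return segregants_and_table[0]


@pytest.fixture(scope="session")
def segregants(segregants_and_table):
    return segregants_and_table[1]


@pytest.fixture(scope="session")
def pool(study_config, reference, segregants):
    return build_pool(study_config, reference, segregants)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, study_config):
    out = tmp_path_factory.mktemp("fixture") / "fx"
    write_fixture(study_config, out)
    return out
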