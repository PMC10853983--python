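import pytest
from hypothesis import settings

from cassfinder.simulate import CassandraSpec, FiveSUnitSpec, five_s_gene

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def unit_spec():
    return FiveSUnitSpec()


@pytest.fixture(scope="session")
def gene(unit_spec):
    """A canonical synthetic 5S rRNA gene (fixed seed)."""
    return five_s_gene(unit_spec, 1)


@pytest.fixture(scope="session")
def shifted_unit_spec():
    return FiveSUnitSpec(cbox_variant="anthemideae_rdna")


@pytest.fixture(scope="session")
def shifted_gene(shifted_unit_spec):
    return five_s_gene(shifted_unit_spec, 1)


@pytest.fixture()
def cassandra_spec():
    return CassandraSpec(ltr_length=200, internal_length=100, divergence=0.0)
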