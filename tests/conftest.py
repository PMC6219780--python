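import pytest

from dnapad import Seeds, SecretKeySet, generate_database


@pytest.fixture(scope="session")
def db():
    """Small synthetic reference-strand database (kilobase strands)."""
    return generate_database(count=10, length=1000, seed=11)


@pytest.fixture()
def secrets():
    """The worked-example secret set (g, mu, code table, primer)."""
    return SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")


@pytest.fixture()
def seeds():
    return Seeds.from_root(2024)
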