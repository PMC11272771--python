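import numpy as np
import pytest
from hypothesis import settings

from apephon.coding import CodingScheme
from apephon.synth import fixture_from_tallies
from apephon.tables import johnny_tallies, renata_tallies

settings.register_profile("default", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return frozenset({"my house", "mother", "hello"})


@pytest.fixture(scope="session")
def strict_scheme(lexicon):
    return CodingScheme(variant="strict", real_word_lexicon=lexicon)


@pytest.fixture(scope="session")
def relabeled_scheme(lexicon):
    return CodingScheme(variant="relabeled", real_word_lexicon=lexicon)


@pytest.fixture(scope="session")
def johnny_fixture():
    return fixture_from_tallies(johnny_tallies(), "johnny")


@pytest.fixture(scope="session")
def renata_fixture():
    return fixture_from_tallies(renata_tallies(), "renata")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
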