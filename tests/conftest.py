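import pytest

from cystcea import ParamSet, make_life_table


@pytest.fixture(scope="session")
def params():
    return ParamSet()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def flat_life_table():
    """Zero-mortality table: isolates the disease process from ageing."""
    return make_life_table("flat", {"q": 0.0}, age_range=(40, 110))
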