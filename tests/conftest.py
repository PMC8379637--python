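import pytest

from poolcost import Subpopulation, austria_nov2020, example_toy_scenario


@pytest.fixture(scope="session")
def austria():
    return austria_nov2020()


@pytest.fixture(scope="session")
def austria_pop(austria):
    return austria.subpopulations


@pytest.fixture(scope="session")
def toy_scenario():
    return example_toy_scenario()


@pytest.fixture(scope="session")
def toy_sub(toy_scenario):
    """Single subpopulation: p = 0.01, b = 1, c = 50."""
    return toy_scenario.subpopulations[0]


@pytest.fixture
def make_sub():
    def _make(p, b=1.0, c=1.0, size=1000, name="sub"):
        return Subpopulation(name=name, size=size, prevalence=p, fp_cost=b, fn_cost=c)

    return _make
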