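import pytest

from haus.fixtures import FixtureSpec, frome_gateway_fixture, generate_pathway_library
from haus.runner import run_scenario


@pytest.fixture(scope="session")
def frome():
    return frome_gateway_fixture()


@pytest.fixture(scope="session")
def frome_baseline_rows(frome):
    return run_scenario(
        frome.scenarios["baseline"],
        frome.pathways,
        frome.population,
        frome.rates,
        frome.unit_values,
    )


@pytest.fixture(scope="session")
def frome_scenario_rows(frome):
    def _run(name):
        return run_scenario(
            frome.scenarios[name],
            frome.pathways,
            frome.population,
            frome.rates,
            frome.unit_values,
        )

    return {name: _run(name) for name in frome.scenarios}


@pytest.fixture(scope="session")
def synthetic_library():
    return generate_pathway_library(FixtureSpec(seed=7, n_pathways=170))
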