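import pytest

from chww_uptake.cohort import build_views
from chww_uptake.eligibility import StudyWindow, build_registry
from chww_uptake.fixtures import load_paper_fixtures
from chww_uptake.simulate import SimConfig, generate_population


@pytest.fixture(scope="session")
def registry():
    return build_registry(StudyWindow())


@pytest.fixture(scope="session")
def paper():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic pilot shared by read-only tests."""
    config = SimConfig(n_households=400, seed=20210701)
    return config, generate_population(config)


@pytest.fixture(scope="session")
def small_views(small_sim, registry):
    _, (patients, _, _) = small_sim
    return build_views(patients, registry)
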