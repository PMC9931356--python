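import pytest

from clinalg.casegen import build_fixture_algorithm, default_profiles, generate_cases


@pytest.fixture(scope="session")
def alg():
    return build_fixture_algorithm()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def cases_small(profiles):
    return generate_cases(profiles, 300, seed=11)
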