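import pytest

from her2cua import Perspective, builtin_base_case, run_all_strategies


@pytest.fixture(scope="session")
def base_params():
    return builtin_base_case()


@pytest.fixture(scope="session")
def public_results(base_params):
    return run_all_strategies(base_params, Perspective.PUBLIC)


@pytest.fixture(scope="session")
def societal_results(base_params):
    return run_all_strategies(base_params, Perspective.SOCIETAL)


@pytest.fixture(scope="session")
def small_psa(base_params):
    """A modest Monte Carlo run shared by the PSA summary tests."""
    from her2cua import run_psa

    return run_psa(base_params, n=60, seed=11, perspective=Perspective.SOCIETAL)
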