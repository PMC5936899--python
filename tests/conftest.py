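import pytest

from climveg import ClimateParams


@pytest.fixture(scope="session")
def params():
    """Default parameter set (gamma left at its default 0.1)."""
    return ClimateParams()


@pytest.fixture(scope="session")
def params_for():
    """Factory: default parameters with a given vegetation death rate."""
    def make(gamma: float) -> ClimateParams:
        return ClimateParams(gamma=gamma)
    return make


@pytest.fixture(scope="session")
def equilibria_cache(params_for):
    """Equilibria per gamma, computed once per session."""
    from climveg import find_equilibria
    cache = {}

    def get(gamma: float):
        if gamma not in cache:
            cache[gamma] = find_equilibria(params_for(gamma))
        return cache[gamma]

    return get
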