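import pytest

from glncycle import (
    LabelingStrategy,
    ModelVariant,
    Strategy,
    default_fluxes,
    default_pools,
    default_protocol,
)


@pytest.fixture(scope="session")
def fluxes():
    return default_fluxes()


@pytest.fixture(scope="session")
def pools():
    return default_pools()


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def full_glc():
    return LabelingStrategy(Strategy.GLC_C1, ModelVariant.FULL)


@pytest.fixture(scope="session")
def simplified_glc():
    return LabelingStrategy(Strategy.GLC_C1, ModelVariant.SIMPLIFIED)
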