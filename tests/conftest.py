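import numpy as np
import pytest

from tfire import (
    PotentialConfig,
    ToySpec,
    build_pem,
    make_toy_complex,
    train_tfire,
)


@pytest.fixture(scope="session")
def toy():
    """Default sequence-specific toy complex (14-bp site, full probe set)."""
    return make_toy_complex(ToySpec())


@pytest.fixture(scope="session")
def toy_potential(toy):
    with np.errstate(all="raise"):
        return train_tfire(toy)


@pytest.fixture(scope="session")
def toy_pem(toy, toy_potential):
    return build_pem(toy_potential, toy)


@pytest.fixture(scope="session")
def small_toy():
    """Shorter template for tests that retrain many times."""
    return make_toy_complex(ToySpec(sequence="GATCCGTA", seed=1))


@pytest.fixture
def plain_config():
    """All corrections off, coarse bins: the minimal potential."""
    return PotentialConfig(use_reweight=False, use_smoothing=False,
                           use_dipolar=False, use_volume_fraction=False)
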