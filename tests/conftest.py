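import numpy as np
import pandas as pd
import pytest

from vaxtrial.design import Village
from vaxtrial.population import GeneratorConfig, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_villages():
    """Two districts: 9 villages (one leftover) and 8 villages."""
    pops_a = [800, 700, 600, 500, 400, 300, 200, 100, 50]
    pops_b = [900, 850, 650, 550, 450, 350, 250, 150]
    villages = [
        Village(f"a{i + 1}", "dA", p) for i, p in enumerate(pops_a)
    ] + [Village(f"b{i + 1}", "dB", p) for i, p in enumerate(pops_b)]
    return villages


def small_config(**overrides):
    """A fast-but-realistic generator configuration for unit tests."""
    defaults = dict(
        n_districts=2,
        villages_per_district=30,
        quads_per_district=5,
        individuals_per_village=15,
        spillover_per_village=2.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def default_trial():
    """One full-size synthetic trial shared across read-only tests."""
    return generate_trial(seed=7)


@pytest.fixture(scope="session")
def small_trial():
    return generate_trial(small_config(), seed=11)
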