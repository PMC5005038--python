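import numpy as np
import pandas as pd
import pytest

from hexdir import city


@pytest.fixture(scope="session")
def layout():
    return city.build_city_layout()


@pytest.fixture(scope="session")
def combos(layout):
    return city.enumerate_combinations(layout)


@pytest.fixture(scope="session")
def combos48(combos):
    return city.apply_exclusions(combos, seed=0)


@pytest.fixture(scope="session")
def trials(combos48):
    return city.generate_design(combos48, seed=1)


@pytest.fixture(scope="session")
def labels(trials, layout):
    return city.label_pairs(trials, layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
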