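import numpy as np
import pytest

from sensorlight.containers import EffectSpec
from sensorlight.searchlight import neighbor_graph
from sensorlight.synth import make_layout, make_stimulus_table, simulate_epochs


@pytest.fixture(scope="session")
def grid3():
    return make_layout(3, 3, 1.0)


@pytest.fixture(scope="session")
def grid4():
    return make_layout(4, 4, 1.0)


@pytest.fixture(scope="session")
def table24():
    return make_stimulus_table(24, seed=7)


@pytest.fixture(scope="session")
def table134():
    return make_stimulus_table(134, seed=3)


@pytest.fixture(scope="session")
def effect_epochs(grid4, table24):
    """One subject with a strong binary word-length effect at 100-200 ms."""
    effect = EffectSpec(
        variable="length_class",
        channels=("CH0000", "CH0001", "CH0101"),
        window_ms=(100.0, 200.0),
        amplitudes={"short": 0.0, "long": 1.5},
    )
    eps = simulate_epochs(
        table24, grid4, [effect],
        noise_sd=1.0, n_subjects=1, n_reps=3, fs=60.0,
        epoch_ms=(-100.0, 400.0), invalid_fraction=0.0,
        artifact_fraction=0.10, seed=2,
    )[0]
    return eps, effect


@pytest.fixture(scope="session")
def graph4(grid4):
    return neighbor_graph(grid4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
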