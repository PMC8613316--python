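import numpy as np
import pytest

from cortexcal import synthgen as sg
from cortexcal import traces as tr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_population():
    """A small noisy population with known event times."""
    cfg = sg.PopulationConfig(n_neurons=5, duration_s=120.0, seed=11)
    F, truth = sg.generate_population(cfg)
    return cfg, F, truth


def dff_of(F_row, fps=10.0):
    return tr.compute_dff(tr.RawTrace(F_row, fps))
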