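import numpy as np
import pytest

from psilat.hypnogram import Hypnogram
from psilat.score import EmbeddingParams
from psilat.simulate import NightConfig, generate_null_windows, henon_first_coordinate
from psilat.surrogates import psi_score


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def default_params():
    return EmbeddingParams()


@pytest.fixture(scope="session")
def null_psi_sample():
    """psi over 200 windows (N=4096, 256 Hz) of the null process.

    The type-I-error surface of the whole method: windows drawn from an
    AR(2) Gaussian process observed through the monotone measurement
    function, exactly the class the surrogates embody.
    """
    cfg = NightConfig()
    psis = []
    for chunk in range(10):
        wins = generate_null_windows(20, seed=60_000 + chunk, config=cfg)
        for i, w in enumerate(wins):
            psis.append(psi_score(w, seed=(60_000, chunk, i)).psi)
    return np.asarray(psis)


@pytest.fixture(scope="session")
def henon_psi_sample():
    """psi over 200 windows of the Henon map's first coordinate."""
    psis = []
    for i in range(200):
        w = henon_first_coordinate(4096, seed=70_000 + i)
        psis.append(psi_score(w, seed=(70_000, i)).psi)
    return np.asarray(psis)


@pytest.fixture
def tiny_hypnogram():
    return Hypnogram(labels=["W"] * 4 + ["N2"] * 4 + ["N3"] * 2)
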