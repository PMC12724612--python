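import numpy as np
import pytest

from clampconf import ObserverParams, SessionDesign, make_clamp_sequence


@pytest.fixture
def design() -> SessionDesign:
    return SessionDesign()


@pytest.fixture
def ma_design() -> SessionDesign:
    return SessionDesign(task="motor_awareness")


@pytest.fixture
def clamp(design) -> np.ndarray:
    return make_clamp_sequence(design)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_observer() -> ObserverParams:
    """Low-noise adapting agent: its spectral structure is essentially exact."""
    return ObserverParams(sigma_m=0.5, sigma_p=1.0, conf_noise_sd=0.5, seed=7)
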