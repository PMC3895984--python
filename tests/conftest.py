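import numpy as np
import pytest

from sbftime import MorrisLecarParams, OscillatorBankSpec, calibrate_bank, make_frequencies


@pytest.fixture
def alpha_small() -> OscillatorBankSpec:
    """Reduced alpha-band bank for fast tests."""
    return OscillatorBankSpec(n_osc=200, f_min=8.0, f_max=12.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ml_params() -> MorrisLecarParams:
    return MorrisLecarParams()


@pytest.fixture(scope="session")
def ml_mini_bank(ml_params):
    """A small calibrated ML bank shared across tests (calibration is slow)."""
    freqs = make_frequencies(OscillatorBankSpec(n_osc=10, f_min=8.0, f_max=12.0))
    return calibrate_bank(freqs, ml_params)
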