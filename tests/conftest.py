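import pytest

from spellersim.experiment import run_calibration
from spellersim.signal_sim import TimingConfig, make_subject_model
from spellersim.speller_fsm import Speller


@pytest.fixture(scope="session")
def timing():
    return TimingConfig()


@pytest.fixture(scope="session")
def speller():
    return Speller()


@pytest.fixture(scope="session")
def zero_noise_subject():
    return make_subject_model(1, 0.0)


@pytest.fixture(scope="session")
def zero_noise_calibration(zero_noise_subject):
    """Calibration (model, curve, chosen sequences) of an idealized
    noiseless recording; shared across tests because it is deterministic."""
    return run_calibration(zero_noise_subject)
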