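import numpy as np
import pytest

import ssvepkit as sk

FREQUENCIES = (6.0, 6.67, 7.5, 10.0)


@pytest.fixture(scope="session")
def hybrid_session():
    """One default-noise PRS-hybrid session shared by read-only tests."""
    cfg = sk.SimulationConfig(seed=11, include_subharmonic=True, n_trials_per_class=3)
    return sk.generate_session(cfg)


@pytest.fixture(scope="session")
def hybrid_epochs(hybrid_session):
    """Bandpassed 1 s epochs from the shared session."""
    rec = sk.bandpass(hybrid_session.recording)
    return sk.epoch_extract(rec, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
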