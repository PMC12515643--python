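import numpy as np
import pytest

import motorstates as ms


@pytest.fixture(scope="session")
def templates16():
    """Five planted templates on the 16-channel motor montage."""
    return ms.make_templates(16, 5, seed=1)


@pytest.fixture(scope="session")
def noisefree_sim(templates16):
    """20 s noise-free simulation with its epoched form."""
    rec, truth = ms.simulate_eeg(templates16, [1.0] * 5, [60.0] * 5,
                                 snr_db=np.inf, fs=500, duration_s=20, seed=2)
    epochs = ms.epoch(rec, 2.0)
    return rec, truth, epochs


@pytest.fixture(scope="session")
def scores():
    return ms.clinical_fixture()
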