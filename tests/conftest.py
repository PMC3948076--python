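import numpy as np
import pytest

from flimcoloc import IRF, DecayModel


@pytest.fixture
def gaussian_irf():
    """Typical confocal TCSPC response: 0.3 ns FWHM pulse at 1 ns."""
    return IRF(kind="gaussian", center_ns=1.0, fwhm_ns=0.3)


@pytest.fixture
def delta_irf():
    return IRF(kind="delta", center_ns=0.0)


@pytest.fixture
def mono_model():
    return DecayModel(components=[(1.0, 2.0)])


@pytest.fixture
def edges_256():
    return np.linspace(0.0, 25.0, 257)
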