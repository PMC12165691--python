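import numpy as np
import pytest

from alphaprf import StimulusDesign, generate_aperture_sequence
from alphaprf.prf import prepare_stimulus


@pytest.fixture(scope="session")
def design():
    return StimulusDesign()


@pytest.fixture(scope="session")
def apertures(design):
    return generate_aperture_sequence(design)


@pytest.fixture(scope="session")
def stim_matrix(apertures):
    """Decimated, spatially coarsened stimulus ready for pRF fitting."""
    return prepare_stimulus(apertures)


@pytest.fixture(scope="session")
def freqs():
    """The 1 Hz analysis grid."""
    return np.arange(1, 251, dtype=float)
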